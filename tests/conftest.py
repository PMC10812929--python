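import pytest
from hypothesis import HealthCheck, settings

from lncflora.pipeline import RunConfig, run_pipeline
from lncflora.synthetic_data import SynthConfig, generate_bundle, write_bundle

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle (the standard study conditions, seed 1)."""
    return generate_bundle(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, d)
    return d


@pytest.fixture(scope="session")
def run_result(bundle_dir, tmp_path_factory):
    """Full pipeline run on the default bundle."""
    outdir = tmp_path_factory.mktemp("run")
    report = run_pipeline(RunConfig(bundle_dir=bundle_dir, outdir=outdir, seed=1))
    return {"outdir": outdir, "report": report}


@pytest.fixture(scope="session")
def truth_qualifying_set(bundle):
    """Transcripts that should survive the default filter cascade, from truth.

    Derived with plain pandas expressions over the truth tables — the
    hand-applied version of the documented rules, independent of the
    package's filter implementation.
    """
    t = bundle.truth_transcripts.set_index("transcript_id").copy()
    expr = bundle.truth_expression.set_index("feature_id")
    t["max_fpkm"] = expr["max_fpkm"]
    keep = (
        (~t["planted_coding"])
        & t["planted_class"].isin(list("uxio"))
        & (t["length"] >= 200)
        & (t["max_fpkm"] >= 0.5)
    )
    return set(t.index[keep])
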