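import pytest

from protomir import PipelineConfig, annotate, preprocess, run_pipeline, simdata


@pytest.fixture(scope="session")
def sim_params():
    return simdata.SimParams(seed=11, n_reads_per_library=20_000)


@pytest.fixture(scope="session")
def bundle(sim_params):
    return simdata.generate_reference(sim_params)


@pytest.fixture(scope="session")
def libraries(bundle, sim_params):
    return {c: simdata.simulate_library(bundle, sim_params, c)
            for c in simdata.CONDITIONS}


@pytest.fixture(scope="session")
def cleaned(libraries, sim_params):
    """(profiles, ledgers) per condition from the simulated libraries."""
    profiles, ledgers = {}, {}
    for cond, lib in libraries.items():
        prof, led = preprocess.clean_reads(
            ((seq, qual) for _rid, seq, qual in lib.reads),
            adapter3=sim_params.adapter3, adapter5=sim_params.adapter5,
            condition=cond,
        )
        profiles[cond], ledgers[cond] = prof, led
    return profiles, ledgers


@pytest.fixture(scope="session")
def annotations(cleaned, bundle):
    profiles, _ = cleaned
    return {c: annotate.classify(p, bundle) for c, p in profiles.items()}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full end-to-end run at moderate depth, shared across tests."""
    cfg = PipelineConfig(outdir=str(tmp_path_factory.mktemp("run")))
    cfg.sim.seed = 1
    cfg.sim.n_reads_per_library = 50_000
    return run_pipeline(cfg)
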