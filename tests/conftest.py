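import pytest

from gstyper import (
    concordance,
    load_packaged_database,
    load_packaged_panel,
    simulate_genotypes,
    type_run,
)
from gstyper.genotyper import AlleleMatcher
from gstyper.simulate import ErrorModel, simulate_reads


@pytest.fixture(scope="session")
def db():
    return load_packaged_database()


@pytest.fixture(scope="session")
def panel(db):
    return load_packaged_panel(db)


@pytest.fixture(scope="session")
def matcher(db, panel):
    return AlleleMatcher(db, panel, "exon_plus_flank", 10)


@pytest.fixture(scope="session")
def matcher_exon_only(db, panel):
    return AlleleMatcher(db, panel, "exon_only", 10)


@pytest.fixture(scope="session")
def validation_run(db, panel):
    """Scaled-down synthetic validation: 20 samples x 3 class I loci at mean
    depth 200 under the default error model (fixed seed)."""
    loci = ["A", "B", "C"]
    truth = simulate_genotypes(
        db, 20, homozygote_rate=0.103, seed=1, loci=loci, mids=sorted(panel.mids)
    )
    run = simulate_reads(
        truth, panel, db, mean_depth=200.0, error_model=ErrorModel(), seed=1
    )
    report = type_run(run.reads, panel, db, run.association, loci=loci)
    summary = concordance(report, truth)
    return {"truth": truth, "run": run, "report": report, "summary": summary}


@pytest.fixture(scope="session")
def clean_run(db, panel):
    """Small noise-free run over all class I loci for exact round trips."""
    loci = ["A", "B", "C"]
    truth = simulate_genotypes(
        db, 6, homozygote_rate=0.1, seed=7, loci=loci, mids=sorted(panel.mids)
    )
    run = simulate_reads(
        truth, panel, db, mean_depth=90.0, error_model=ErrorModel.noise_free(), seed=7
    )
    return {"truth": truth, "run": run, "loci": loci}
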