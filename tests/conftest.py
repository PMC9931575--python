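import numpy as np
import pytest

from cge import LocusDesign, SimConfig, TagScheme, demo_locus, simulate_experiment


@pytest.fixture(scope="session")
def design() -> LocusDesign:
    """Synthetic E-box-style locus: 150-nt amplicon, CACGTG -> TATTTA."""
    return demo_locus(seed=7)


@pytest.fixture(scope="session")
def second_design() -> LocusDesign:
    """A second locus with a distinct prefix, for multi-locus tests."""
    return demo_locus(locus_name="EBOX_DEMO_2", seed=11)


@pytest.fixture(scope="session")
def null_sim(design):
    """Small error-free experiment with no fitness effect (shared across tests)."""
    cfg = SimConfig(
        design=design,
        n_cells_transfected=5_000,
        fitness_effect=0.0,
        read_depths={"baseline": 50_000, "endpoint": 50_000},
        seq_error_rate=0.0,
        lineage_rate_sd=0.0,
        rng_seed=42,
    )
    return cfg, simulate_experiment(cfg)


def make_read(design: LocusDesign, variant: str, tag: str) -> str:
    """Amplicon read carrying the given variant and tag, otherwise reference."""
    a = design.amplicon_ref
    f = design.flank_len
    center = design.original_seq if variant == "original" else design.mutant_seq
    return (
        a[: design.variant_start - f]
        + tag[:f]
        + center
        + tag[f:]
        + a[design.variant_end + f :]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
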