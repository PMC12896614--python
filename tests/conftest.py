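import numpy as np
import pandas as pd
import pytest

from clonediff.panel import ClonePanel
from clonediff.simulate import (
    DEEffect,
    PanelConfig,
    TruthTable,
    generate_panel,
    simulate_atac,
    simulate_expression,
)

PAPER_PANEL = PanelConfig(n_wt=4, n_exon4_high=3, n_exon4_low=4, n_exon6=5, n_double=8, seed=1)


@pytest.fixture(scope="session")
def panel() -> ClonePanel:
    """The 24-clone study-design panel (4 WT / 3+4 exon-4 / 5 exon-6 / 8 double)."""
    return generate_panel(PAPER_PANEL)


@pytest.fixture(scope="session")
def expression_sim(panel):
    """A small simulated expression data set with two planted effects."""
    truth = TruthTable(
        de_genes=(
            DEEffect("G0005", "H4:2-vs-0", 2.0),
            DEEffect("G0010", "H4:2-vs-0", -1.5),
        )
    )
    return simulate_expression(
        panel, n_genes=60, transcripts_per_gene=2, truth=truth,
        dispersion=0.4, seed=7, dropped_fraction=0.1,
    )


@pytest.fixture(scope="session")
def atac_sim(panel):
    from clonediff.simulate import GradientPeak

    truth = TruthTable(
        gradient_peaks=(GradientPeak("P0003", 150.0),),
        outlier_observations=(("P0010", "C05"),),
    )
    calls = simulate_atac(panel, n_peaks=40, truth=truth, seed=11)
    return truth, calls
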