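import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import nds_synergy as ns

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mic_panel_2():
    """Two drugs, MIC-normalized at 1 ug/mL."""
    return ns.DrugPanel(
        tuple(ns.DrugSpec(n, mic=1.0, normalization_label="MIC") for n in "AB")
    )


@pytest.fixture(scope="session")
def mic_panel_4():
    return ns.DrugPanel(
        tuple(ns.DrugSpec(n, mic=1.0, normalization_label="MIC") for n in "ABCD")
    )


@pytest.fixture(scope="session")
def ecoli_panel():
    return ns.ecoli_mg1655_panel("breakpoint")


def diagonal_table(panel, ladder, effective_fn):
    """Build an EffectivenessTable from a rule (subset, ratio) -> bool."""
    from itertools import combinations

    rows = []
    for k in range(1, len(panel) + 1):
        for subset in combinations(panel.names, k):
            key = ns.subset_key(subset, panel)
            for j, c in enumerate(ladder.ratios, 1):
                eff = effective_fn(frozenset(subset), c)
                rows.append((key, j, c, 0.0 if eff else 10.0, eff, 1))
    df = pd.DataFrame(
        rows,
        columns=["subset", "step_index", "ratio", "measure_value", "effective", "n_replicates"],
    )
    return ns.EffectivenessTable(df, ns.EffectivenessThreshold("AUGC", 1.0))


@pytest.fixture(scope="session")
def quarter_mic_pair_table(mic_panel_2):
    """The canonical cutoff scenario: singles effective only at their MIC,
    the pair effective along its diagonal down to 1/4 MIC."""
    ladder = ns.build_ladder(1, 2, 4)

    def rule(subset, c):
        return c >= (1.0 if len(subset) == 1 else 0.25)

    return diagonal_table(mic_panel_2, ladder, rule)
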