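"""Built-in example panels.

The eight-antibiotic *E. coli* MG-1655 panel covers a deliberately broad set
of drug classes (beta-lactams, an amphenicol, a quinolone, aminoglycosides,
an antifolate). Breakpoints are EUCAST susceptible breakpoints for
Enterobacterales; MICs are strain-specific broth-microdilution values.
All concentrations are ug/mL.
"""

from .panel import DrugPanel, DrugSpec

_ECOLI_MG1655 = (
    # (name, asm_code, breakpoint, mic)
    ("Ampicillin", "AMP", 8.0, 16.0),
    ("Aztreonam", "ATM", 1.0, 0.25),
    ("Ceftazidime", "CAZ", 1.0, 0.25),
    ("Chloramphenicol", "CHL", 8.0, 8.0),
    ("Ciprofloxacin", "CIP", 0.25, 0.015625),
    ("Gentamicin", "GEN", 2.0, 0.5),
    ("Trimethoprim", "TMP", 4.0, 0.25),
    ("Tobramycin", "TOB", 2.0, 0.5),
)


def ecoli_mg1655_panel(normalization: str = "breakpoint") -> DrugPanel:
    """Example eight-antibiotic panel for *E. coli* MG-1655.

    Parameters
    ----------
    normalization : {"breakpoint", "MIC"}
        Whether N_i is the EUCAST susceptible breakpoint (strain-independent,
        clinically oriented) or the strain MIC (comparable to FICI-style
        screens).
    """
    return DrugPanel(
        tuple(
            DrugSpec(
                name=name,
                asm_code=code,
                mic=mic,
                breakpoint=bp,
                normalization_label=normalization,
            )
            for name, code, bp, mic in _ECOLI_MG1655
        ),
        normalization,
    )
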