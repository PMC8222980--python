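"""Published worked-example data for the statistics pipeline.

Reported plasma clotting times (mean ± SD of triplicates, seconds) of 18
*Vipera* venoms at the curve-maximum final concentration of 20 µg/ml,
together with the venom pairs reported as not significantly different
(p > 0.05) in the accompanying one-way ANOVA.  These summaries are the
only replicate statistics published for the assay and serve as the
worked example for the summary-statistics ANOVA/Tukey route.
"""

from __future__ import annotations

from .stats import GroupSummary

#: (label, mean clotting time s, SD s); n = 3 throughout.
_VIPERA_CLOTTING_ROWS = (
    ("V. ammodytes (Lake Skadar, Montenegro)", 15.4, 0.9),
    ("V. ammodytes (Ada Island, Montenegro)", 16.0, 0.1),
    ("V. ammodytes (Maribor, Slovenia)", 18.4, 1.9),
    ("V. ammodytes (Slunj, Croatia)", 20.4, 0.5),
    ("V. ammodytes (Krk Island, Croatia)", 23.0, 0.6),
    ("V. berus (Slovenia)", 23.9, 0.1),
    ("V. berus (Sneznik Mountain, Slovenia)", 23.9, 0.1),
    ("V. latastei gaditana (Spain)", 26.7, 0.3),
    ("V. aspis hugyi (Italy)", 28.7, 0.2),
    ("V. a. meridionalis (Greece)", 30.3, 0.4),
    ("V. berus (Norway)", 33.0, 2.4),
    ("V. kaznakovi (Turkey)", 35.3, 0.4),
    ("V. renardi (Russia)", 44.1, 0.4),
    ("V. a. montandoni (Bulgaria)", 66.2, 3.4),
    ("V. aspis aspis (France)", 98.9, 0.3),
    ("V. transcaucasiana (Turkey)", 107.8, 1.4),
    ("V. nikolskii (Russia)", 179.7, 0.3),
    ("V. latastei latastei (Spain)", 359.8, 4.5),
)


def vipera_clotting_summaries(n: int = 3) -> list[GroupSummary]:
    """The 18 published *Vipera* clotting-time summaries at 20 µg/ml."""
    return [GroupSummary(label=label, n=n, mean=mean, sd=sd)
            for label, mean, sd in _VIPERA_CLOTTING_ROWS]


#: Venom pairs reported as NOT significantly different (p > 0.05); every
#: other pair among the 18 groups was reported as significantly different.
VIPERA_NONSIGNIFICANT_PAIRS = frozenset(
    frozenset(pair) for pair in (
        ("V. ammodytes (Krk Island, Croatia)", "V. ammodytes (Slunj, Croatia)"),
        ("V. ammodytes (Krk Island, Croatia)", "V. berus (Slovenia)"),
        ("V. ammodytes (Krk Island, Croatia)", "V. berus (Sneznik Mountain, Slovenia)"),
        ("V. ammodytes (Krk Island, Croatia)", "V. latastei gaditana (Spain)"),
        ("V. ammodytes (Maribor, Slovenia)", "V. ammodytes (Ada Island, Montenegro)"),
        ("V. ammodytes (Maribor, Slovenia)", "V. ammodytes (Lake Skadar, Montenegro)"),
        ("V. ammodytes (Maribor, Slovenia)", "V. ammodytes (Slunj, Croatia)"),
        ("V. ammodytes (Ada Island, Montenegro)", "V. ammodytes (Lake Skadar, Montenegro)"),
        ("V. ammodytes (Ada Island, Montenegro)", "V. ammodytes (Slunj, Croatia)"),
        ("V. ammodytes (Slunj, Croatia)", "V. berus (Slovenia)"),
        ("V. ammodytes (Slunj, Croatia)", "V. berus (Sneznik Mountain, Slovenia)"),
        ("V. a. meridionalis (Greece)", "V. aspis hugyi (Italy)"),
        ("V. a. meridionalis (Greece)", "V. berus (Norway)"),
        ("V. a. meridionalis (Greece)", "V. latastei gaditana (Spain)"),
        ("V. aspis hugyi (Italy)", "V. berus (Slovenia)"),
        ("V. aspis hugyi (Italy)", "V. berus (Norway)"),
        ("V. aspis hugyi (Italy)", "V. latastei gaditana (Spain)"),
        ("V. berus (Norway)", "V. kaznakovi (Turkey)"),
        ("V. berus (Slovenia)", "V. berus (Sneznik Mountain, Slovenia)"),
        ("V. berus (Slovenia)", "V. latastei gaditana (Spain)"),
        ("V. berus (Sneznik Mountain, Slovenia)", "V. latastei gaditana (Spain)"),
    )
)

#: Spontaneous (no-venom) plasma clotting time, mean ± SD of triplicates.
SPONTANEOUS_CLOTTING_S = (645.2, 9.8)
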