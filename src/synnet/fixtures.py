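"""Bundled reference data used by tests, docs and the acceptance report.

``demo_treebank`` is the canonical two-sentence worked example ("He reads
books" / "He reads books at school") whose five-vertex network has known
geodesics, zero clustering, density 0.4 and centralization 0.4375.

``reference_panel`` is the published ten-network parameter table (two
modalities x four learner levels + native references) on which the
statistical battery's expected values are anchored.
"""

from __future__ import annotations

import pandas as pd

from synnet.treebank import CorpusMeta, Sentence, Token, Treebank


def demo_treebank() -> Treebank:
    """Two-sentence worked example; 8 tokens, 5 word types, 4 merged edges."""
    s1 = Sentence(
        sentence_id="s1",
        tokens=(
            Token(order=1, form="Ta", pos="r", governor_order=2, relation="SBV"),
            Token(order=2, form="Kan", pos="v", governor_order=0, relation="HED"),
            Token(order=3, form="Shu", pos="n", governor_order=2, relation="VOB"),
        ),
    )
    s2 = Sentence(
        sentence_id="s2",
        tokens=(
            Token(order=1, form="Ta", pos="r", governor_order=4, relation="SBV"),
            Token(order=2, form="Zai", pos="p", governor_order=4, relation="ADV"),
            Token(order=3, form="Xuexiao", pos="n", governor_order=2, relation="POB"),
            Token(order=4, form="Kan", pos="v", governor_order=0, relation="HED"),
            Token(order=5, form="Shu", pos="n", governor_order=4, relation="VOB"),
        ),
    )
    return Treebank(
        sentences=[s1, s2],
        meta=CorpusMeta(modality="written", level=1, label="demo"),
    )


_PANEL_ROWS = [
    # label, modality, level, N, tokens, gamma_prime, fit_R2, k_mean, C, L, ND, NC
    ("W1", "written", 1, 1001, 5167, 1.057, 0.9659, 6.110, 0.219, 3.019, 0.009, 0.190),
    ("W2", "written", 2, 1168, 5154, 1.132, 0.9713, 5.914, 0.211, 3.008, 0.007, 0.197),
    ("W3", "written", 3, 1227, 5085, 1.329, 0.9804, 5.514, 0.211, 3.062, 0.006, 0.231),
    ("W4", "written", 4, 1367, 5224, 1.330, 0.9761, 5.482, 0.162, 3.082, 0.005, 0.246),
    ("WN", "written", "native", 1710, 5164, 1.481, 0.9727, 4.815, 0.131, 3.651, 0.003, 0.291),
    ("O1", "oral", 1, 616, 4910, 1.243, 0.9711, 6.979, 0.333, 3.298, 0.020, 0.144),
    ("O2", "oral", 2, 672, 4986, 1.272, 0.9643, 6.906, 0.290, 3.331, 0.018, 0.152),
    ("O3", "oral", 3, 733, 5142, 1.272, 0.9711, 6.821, 0.280, 3.290, 0.016, 0.169),
    ("O4", "oral", 4, 773, 5319, 1.282, 0.9613, 6.617, 0.264, 3.174, 0.015, 0.171),
    ("ON", "oral", "native", 1037, 5094, 1.307, 0.9808, 6.002, 0.204, 3.279, 0.008, 0.198),
]


def reference_panel() -> pd.DataFrame:
    """The published ten-network parameter table as a DataFrame."""
    return pd.DataFrame(
        _PANEL_ROWS,
        columns=[
            "label",
            "modality",
            "level",
            "N",
            "token_count",
            "gamma_prime",
            "fit_R2",
            "k_mean",
            "C",
            "L",
            "ND",
            "NC",
        ],
    )
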