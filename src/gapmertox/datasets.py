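"""Bundled reference tables.

``hepatotoxic_screen_table`` is the published screening table of the five
14-mer LNA gapmers that elevated serum AST/ALT above 100 U/l in vivo
(mice, 20 mg/kg intravenous, 96 h), with the printed TGC/TCC motif counts.
It is the standard worked example for motif counting and the
hepatotoxicity call, and the ASO sequences are real inputs for scans.
"""

from __future__ import annotations

import pandas as pd

from gapmertox.tox import ToxRecord

__all__ = ["hepatotoxic_screen_table", "screen_tox_records", "TS1_SEQUENCE"]

#: Sequence of TS1, the most hepatotoxic gapmer of the screen.
TS1_SEQUENCE = "GTTATGCCACCCTA"

_ROWS = [
    ("TS1", "GTTATGCCACCCTA", 1, 0, 9437.0, 15602.0),
    ("TS2", "GTCCGCATGCCTAA", 1, 1, 1364.0, 1617.0),
    ("TS3", "GATATGCCCTACTA", 1, 0, 448.0, 1061.0),
    ("TS4", "GTATGCCTCCGTTA", 1, 1, 2164.0, 600.0),
    ("TS5", "GCTATGTTAGTCCG", 0, 1, 287.0, 291.0),
]


def hepatotoxic_screen_table() -> pd.DataFrame:
    """The five hepatotoxic screen hits: sequence, motif counts, AST/ALT (U/l)."""
    return pd.DataFrame(_ROWS, columns=["aso_id", "sequence", "tgc", "tcc", "ast", "alt"])


def screen_tox_records() -> list[ToxRecord]:
    """The screening table as :class:`~gapmertox.tox.ToxRecord` objects."""
    return [
        ToxRecord(aso_id=aso_id, ast=ast, alt=alt, dose=20.0, n_animals=2)
        for aso_id, _, _, _, ast, alt in _ROWS
    ]
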