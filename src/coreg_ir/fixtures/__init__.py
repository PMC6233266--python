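"""Packaged desk-scale fixtures.

``table1.tsv`` transcribes the published candidate-gene table: per-gene
RelA/p53 binding flags at 2 h and 4 h after 10 Gy, fold changes at 4 and
10 Gy with significance marks, and siRELA/siCTR and siTP53/siCTR expression
ratios. ``validation_qpcr.tsv`` encodes the qualitative qPCR/ChIP-qPCR
validation outcomes for the five follow-up candidates (silencing-effect
directions and whether radiation-induced binding of each TF was confirmed).
"""

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    df = _load("table1.tsv")
    assert len(df) == 28, "table fixture must hold 28 genes"
    return df


def load_validation() -> pd.DataFrame:
    return _load("validation_qpcr.tsv")
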