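"""Small packaged reference tables.

``load_confirmed_hits`` returns the published table of the 11 confirmed hit
compounds from the 1280-compound Prestwick single-dose screen on acidosis-
adapted HCT116 colon carcinoma cells, with each compound's screen-stage
percent inhibition and therapeutic class. Note one compound (Thimerosal) is
printed at 66% inhibition although the screen's hit threshold was 70%; the
table reproduces the published values as-is.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_confirmed_hits"]


def load_confirmed_hits() -> pd.DataFrame:
    """The 11 confirmed Prestwick screen hits (compound, pct_inhibition, group)."""
    ref = resources.files("acidscreen").joinpath("data/prestwick_confirmed_hits.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")
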