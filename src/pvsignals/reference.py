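"""Published VigiBase summary counts for tramadol respiratory depression.

These tables hold the summary statistics printed by a worldwide
spontaneous-reporting (VigiBase, data lock January 2021) study of
tramadol and tramadol/paracetamol: demographic stratum counts, per-term
disproportionality results for the 19 narrow-scope ACRD preferred terms,
and 2xk factor cross-tabulations of ACRD status.  The raw report-level
database is access-restricted, so these counts are the only public anchor;
:func:`pvsignals.disproportionality.reconstruct_table` rebuilds full 2x2
tables from them for consistency checks.

One printed count is corrected here: the consumer-reporter count is stored
as 27,818 (the printed 17,818 is inconsistent with both its printed
percentage, 19.8%, and the reporter-column total).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Total reports in the source database at data lock.
N_DATABASE = 23_811_236
#: Suspected/interacting reports for each index drug.
N_TRAMADOL = 140_721
N_COMBINATION = 51_401
#: ACRD cases among those reports.
N_ACRD_TRAMADOL = 1_126
N_ACRD_COMBINATION = 108

_DRUG_KEYS = {"tramadol": "tramadol", "tramadol/paracetamol": "combination"}


def _load(name: str) -> pd.DataFrame:
    with resources.files("pvsignals.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"], keep_default_na=False)


def demographics_summary() -> pd.DataFrame:
    """Stratum counts (sex/age/reporter/serious/region/year) for all and
    ACRD reports of each index drug."""
    return _load("tramadol_demographics.tsv")


def disproportionality_summary(drug: str | None = None) -> pd.DataFrame:
    """Published per-term n/PRR/ROR/IC025 over the full database.

    ``drug`` may be "tramadol" or "tramadol/paracetamol" to filter.
    """
    frame = _load("tramadol_disproportionality.tsv")
    if drug is not None:
        if drug not in _DRUG_KEYS:
            raise ValueError(f"unknown index drug {drug!r}")
        frame = frame[frame["drug"] == drug].reset_index(drop=True)
    return frame


def factor_summary(factor: str | None = None) -> pd.DataFrame:
    """Published ACRD / non-ACRD counts per factor category for tramadol."""
    frame = _load("tramadol_factors.tsv")
    if factor is not None:
        frame = frame[frame["factor"] == factor].reset_index(drop=True)
        if frame.empty:
            raise ValueError(f"unknown factor {factor!r}")
    return frame
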