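"""Reference model-fit tables from the published Mytilidae selection screen.

The shipped TSVs carry the reported CODEML log-likelihoods and omega
estimates for the 12 mitochondrial protein-coding genes: the one-ratio vs
three-ratios branch screen (shallow-sea / deep-sea / freshwater classes)
and the freshwater branch-site screen.  They are inputs for likelihood-
ratio-test arithmetic and for comparisons against fits this package
produces; the full 44-taxon alignments behind them are not redistributed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .selection import LrtResult, lrt
from .selection import ModelFit as _ModelFit


def _read(name: str) -> pd.DataFrame:
    with resources.files("mytilomito.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def branch_fits() -> pd.DataFrame:
    """One-ratio vs three-ratios reference lnL and omega per gene."""
    return _read("mytilidae_branch_fits.tsv")


def branch_site_fits() -> pd.DataFrame:
    """Freshwater branch-site reference lnL per gene (alternative and null)."""
    return _read("mytilidae_branch_site_fits.tsv")


def _pseudo_fit(lnL: float) -> _ModelFit:
    return _ModelFit(
        lnL=lnL, params=None, n_free_params=0, converged=True, model_tag="reference"
    )


def branch_lrt(gene: str) -> LrtResult:
    """LRT of three-ratios vs one-ratio from the reference lnL values (df 2)."""
    df = branch_fits().set_index("gene")
    row = df.loc[gene]
    return lrt(
        _pseudo_fit(row["lnL_one_ratio"]), _pseudo_fit(row["lnL_three_ratios"]), df=2
    )


def branch_site_lrt(gene: str) -> LrtResult:
    """LRT of the branch-site alternative vs null from reference lnL (df 1)."""
    df = branch_site_fits().set_index("gene")
    row = df.loc[gene]
    return lrt(_pseudo_fit(row["lnL_null"]), _pseudo_fit(row["lnL_alternative"]), df=1)
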