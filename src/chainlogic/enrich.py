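"""Dataset summaries and relative-enrichment statistics for logic rules.

Given a collection of regulatory logic rules (one Boolean function per
(model, node) pair), this module tabulates per-input-count class
memberships and tests whether a sub-type ``T_s`` (say chain-1) is
over-represented within its englobing type ``T`` (say the NCFs) beyond
what uniform sampling from ``T`` would give:

    E_R = (f_s1 / f_1) / (f_s0 / f_0)

where ``f_s1, f_1`` are dataset fractions of ``T_s`` and ``T`` and
``f_s0, f_0`` the corresponding theoretical fractions among all k-input
functions.  Under the null (uniform draws within T), the number of
``T_s`` members among the ``M_T`` dataset functions of type ``T`` is
binomial with success probability ``f_R = |T_s| / |T|``; the reported
p-value is the inclusive upper tail ``P(m' >= m)``.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bfcore import BooleanFunction
from .chainclass import Label, classify
from . import chaincount

__all__ = [
    "BFRecord",
    "summarize_dataset",
    "relative_enrichment",
    "enrichment_pvalue",
    "enrichment_report",
]


@dataclass(frozen=True)
class BFRecord:
    """One regulatory logic rule extracted from a model."""

    source: str
    node: str
    function: BooleanFunction

    @property
    def k(self) -> int:
        return self.function.k


def _label_counts(records) -> dict:
    """Per-k Counter of classification labels (cached per truth table)."""
    cache: dict = {}
    per_k: dict = {}
    for rec in records:
        key = (rec.k, rec.function.outputs.tobytes())
        if key not in cache:
            cache[key] = classify(rec.function).label
        lab = cache[key]
        bucket = per_k.setdefault(rec.k, {"labels": [], "odd": 0, "even": 0})
        bucket["labels"].append(lab)
        if rec.function.bias % 2:
            bucket["odd"] += 1
        else:
            bucket["even"] += 1
    return per_k


def summarize_dataset(records: Sequence[BFRecord]) -> pd.DataFrame:
    """Per-k table of class counts.

    Columns: total, odd_bias, even_bias, ncf, chf0, chf1, chf_both, chfu,
    ncf_non_chfu.  The chf0/chf1 columns include the k <= 2 functions that
    belong to both chain classes; chfu counts each generalized chain
    function once, so chf0 + chf1 - chf_both + ncf_non_chfu = ncf.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record collection")
    per_k = _label_counts(records)
    rows = []
    for k in sorted(per_k):
        labs = per_k[k]["labels"]
        n = len(labs)
        c = {lab: 0 for lab in Label}
        for lab in labs:
            c[lab] += 1
        chfu = c[Label.CHF0] + c[Label.CHF1] + c[Label.CHF_BOTH]
        rows.append(
            {
                "k": k,
                "total": n,
                "odd_bias": per_k[k]["odd"],
                "even_bias": per_k[k]["even"],
                "ncf": chfu + c[Label.NCF_NON_CHFU],
                "chf0": c[Label.CHF0] + c[Label.CHF_BOTH],
                "chf1": c[Label.CHF1] + c[Label.CHF_BOTH],
                "chf_both": c[Label.CHF_BOTH],
                "chfu": chfu,
                "ncf_non_chfu": c[Label.NCF_NON_CHFU],
            }
        )
    return pd.DataFrame(rows).set_index("k")


def relative_enrichment(f_s1: float, f_1: float, f_s0: float, f_0: float) -> float:
    """E_R = (f_s1 / f_1) / (f_s0 / f_0); NaN when a denominator vanishes."""
    if f_1 <= 0 or f_s0 <= 0 or f_0 <= 0:
        return float("nan")
    return (f_s1 / f_1) / (f_s0 / f_0)


def enrichment_pvalue(M_T: int, m: int, f_R: float) -> float:
    """Inclusive binomial upper tail P(m' >= m) with m' ~ Binom(M_T, f_R)."""
    if not 0 <= m <= M_T:
        raise ValueError(f"m={m} outside 0..{M_T}")
    if not 0 <= f_R <= 1:
        raise ValueError(f"f_R={f_R} outside [0, 1]")
    if m == 0:
        return 1.0
    return float(stats.binom.sf(m - 1, M_T, f_R))


_SUBTYPE_COLUMN = {
    "NCF": "ncf",
    "CHF0": "chf0",
    "CHF1": "chf1",
    "CHFU": "chfu",
    "NCF_NON_CHFU": "ncf_non_chfu",
}


def enrichment_report(
    records: Sequence[BFRecord],
    pairs: Iterable[tuple] = (("NCF", "CHF0"), ("NCF", "CHF1"), ("NCF", "CHFU")),
    kmax: int = 10,
) -> pd.DataFrame:
    """Relative enrichment of sub-types, one row per (k, T, T_s).

    ``pairs`` are (englobing type, sub-type) names among ALL, NCF, CHF0,
    CHF1, CHFU, NCF_NON_CHFU.  Theoretical fractions come from the exact
    class cardinalities.  For k <= 2 every NCF is a generalized chain
    function, so chain-within-NCF rows there carry ``defined = False``.
    ``kmax`` mirrors the usual restriction of dataset analyses to rules
    with at most 10 inputs.
    """
    summary = summarize_dataset(records)
    rows = []
    for k in summary.index:
        if k > kmax:
            continue
        n_all = 2 ** (2**k)
        total = int(summary.loc[k, "total"])
        for T, Ts in pairs:
            T, Ts = T.upper(), Ts.upper()
            M_T = total if T == "ALL" else int(summary.loc[k, _SUBTYPE_COLUMN[T]])
            m = int(summary.loc[k, _SUBTYPE_COLUMN[Ts]])
            size_T = chaincount.class_size(k, T)
            size_Ts = chaincount.class_size(k, Ts)
            defined = True
            if k <= 2 and T != "ALL" and Ts in ("CHF0", "CHF1", "CHFU"):
                defined = False  # sub-type coincides with (or exhausts) T
            if M_T == 0 or size_T == 0 or size_Ts == 0:
                defined = False
            f_1 = M_T / total
            f_s1 = m / total
            f_0 = size_T / n_all
            f_s0 = size_Ts / n_all
            f_R = size_Ts / size_T if size_T else float("nan")
            if defined:
                e_r = relative_enrichment(f_s1, f_1, f_s0, f_0)
                pval = enrichment_pvalue(M_T, m, f_R)
            else:
                e_r = float("nan")
                pval = float("nan")
            rows.append(
                {
                    "k": k,
                    "T": T,
                    "T_s": Ts,
                    "M_T": M_T,
                    "m": m,
                    "f_1": f_1,
                    "f_s1": f_s1,
                    "f_0": f_0,
                    "f_s0": f_s0,
                    "f_R": f_R,
                    "E_R": e_r,
                    "p_value": pval,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)
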