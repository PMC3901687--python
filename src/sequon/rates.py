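"""Site-number-stratified divergence of homolog pairs and SNP N/S ratios.

Homolog pairs arrive pre-aligned (gapped amino-acid FASTA); identity is the
fraction of matching residues over columns where neither sequence is
gapped, d_aa = 1 − identity is the observed fractional difference, and the
Poisson-corrected mean substitution fraction is K_aa = −ln(1 − d_aa).
Pairs are grouped by the sequon count of their designated reference
sequence and the identity-vs-site-number trend is fit by OLS on bin means
(per-gene mode available), separately per compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .genetic_code import InputError
from .scan import find_sites

GAP = "-"


@dataclass(frozen=True)
class HomologPair:
    """A pre-aligned homolog pair; ``aligned_a`` is the reference."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    compartment: str = "unlabeled"
    site_number: Optional[int] = None

    def __post_init__(self) -> None:
        a = self.aligned_a.upper()
        b = self.aligned_b.upper()
        object.__setattr__(self, "aligned_a", a)
        object.__setattr__(self, "aligned_b", b)
        if len(a) != len(b):
            raise InputError(f"{self.id_a}/{self.id_b}: aligned lengths differ")
        if self.site_number is None:
            object.__setattr__(
                self, "site_number", len(find_sites(a.replace(GAP, "")))
            )

    @property
    def ids(self) -> Tuple[str, str]:
        return (self.id_a, self.id_b)


def pairwise_identity(pair: HomologPair) -> float:
    """Fraction of identical residues over columns non-gap in both sequences."""
    matches = total = 0
    for x, y in zip(pair.aligned_a, pair.aligned_b):
        if x == GAP or y == GAP:
            continue
        total += 1
        matches += x == y
    if total == 0:
        raise InputError(f"{pair.id_a}/{pair.id_b}: no non-gap aligned columns")
    return matches / total


def substitution_rate(d_aa: float) -> float:
    """Poisson-corrected substitution fraction K_aa = −ln(1 − d_aa)."""
    if not 0.0 <= d_aa < 1.0:
        raise InputError("d_aa must be in [0, 1)")
    return -math.log1p(-d_aa)


def divergence_from_rate(k_aa: float) -> float:
    """Inverse transform d_aa = 1 − exp(−K_aa)."""
    if k_aa < 0:
        raise InputError("K_aa must be >= 0")
    return -math.expm1(-k_aa)


@dataclass(frozen=True)
class RateSummary:
    """Per-bin divergence summary."""

    site_number: int
    compartment: str
    n: int
    identity: float
    d_aa: float
    k_aa: float


def summarize_rates(pairs: Iterable[HomologPair]) -> List[RateSummary]:
    """Mean identity, d_aa and K_aa per (compartment, site-number) bin."""
    df = pd.DataFrame(
        {
            "compartment": p.compartment,
            "site_number": p.site_number,
            "identity": pairwise_identity(p),
        }
        for p in pairs
    )
    if df.empty:
        raise InputError("no homolog pairs supplied")
    out = []
    for (comp, s), grp in df.groupby(["compartment", "site_number"]):
        ident = float(grp["identity"].mean())
        d = 1.0 - ident
        out.append(RateSummary(
            site_number=int(s), compartment=comp, n=len(grp),
            identity=ident, d_aa=d, k_aa=substitution_rate(min(d, 1 - 1e-12)),
        ))
    return out


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    stderr: float
    pearson_r: float
    pearson_p: float
    n_bins: int


def slope_by_site_number(
    pairs: Iterable[HomologPair],
    per_gene: bool = False,
    min_bin_n: int = 3,
) -> Dict[str, SlopeFit]:
    """Linear slope of identity vs site number, fitted per compartment.

    By default the regression runs on bin means (one point per site-number
    bin, matching how stratified identity trends are usually drawn),
    weighted by bin occupancy so near-empty high-site-number bins do not
    dominate; bins with fewer than ``min_bin_n`` pairs are dropped
    outright.  ``per_gene`` fits on the individual pairs instead.  The
    Pearson r/p reported alongside are the unweighted bin-mean
    correlation, as identity-vs-site-number figures usually quote.  The
    dictionary additionally carries ``"difference"`` = secretory −
    cytosolic slope when both compartments are present.
    """
    pairs = list(pairs)
    fits: Dict[str, SlopeFit] = {}
    for comp in sorted({p.compartment for p in pairs}):
        sub = [p for p in pairs if p.compartment == comp]
        if per_gene:
            x = np.array([p.site_number for p in sub], dtype=float)
            y = np.array([pairwise_identity(p) for p in sub])
            w = np.ones_like(x)
        else:
            summ = [r for r in summarize_rates(sub) if r.n >= min_bin_n]
            x = np.array([r.site_number for r in summ], dtype=float)
            y = np.array([r.identity for r in summ])
            w = np.array([r.n for r in summ], dtype=float)
        if len(np.unique(x)) < 3:
            raise InputError(
                f"compartment {comp!r}: need >=3 site-number bins, "
                f"got {len(np.unique(x))}"
            )
        wls = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        r, p = stats.pearsonr(x, y)
        fits[comp] = SlopeFit(
            slope=float(wls.params[1]), intercept=float(wls.params[0]),
            stderr=float(wls.bse[1]), pearson_r=float(r),
            pearson_p=float(p), n_bins=len(np.unique(x)),
        )
    if "secretory" in fits and "cytosolic" in fits:
        diff = fits["secretory"].slope - fits["cytosolic"].slope
        se = math.hypot(fits["secretory"].stderr, fits["cytosolic"].stderr)
        fits["difference"] = SlopeFit(
            slope=diff, intercept=float("nan"), stderr=se,
            pearson_r=float("nan"), pearson_p=float("nan"),
            n_bins=min(fits["secretory"].n_bins, fits["cytosolic"].n_bins),
        )
    return fits


def normalized_slope(fit: SlopeFit, separation_time: float) -> float:
    """Slope difference per unit separation time (cross-species comparison)."""
    if separation_time <= 0:
        raise InputError("separation time must be positive")
    return fit.slope / separation_time


# ---------------------------------------------------------------------------
# SNP N/S ratios


def ns_ratio(variants: pd.DataFrame,
             group_cols: Sequence[str] = ("compartment", "site_number"),
             alpha: float = 0.05) -> pd.DataFrame:
    """Nonsynonymous/synonymous variant-count ratio per group with binomial CI.

    ``variants`` needs a ``consequence`` column with values
    {"nonsynonymous", "synonymous"} plus the grouping columns.  The CI is
    Clopper-Pearson on the nonsynonymous proportion, transformed to the
    ratio scale; groups with zero synonymous variants get ``ratio`` = NaN
    and ``undefined`` = True.
    """
    if variants.empty:
        raise InputError("empty variant table")
    bad = set(variants["consequence"]) - {"nonsynonymous", "synonymous"}
    if bad:
        raise InputError(f"unknown consequence values {sorted(bad)}")
    rows = []
    for key, grp in variants.groupby(list(group_cols)):
        if not isinstance(key, tuple):
            key = (key,)
        n = int((grp["consequence"] == "nonsynonymous").sum())
        s = int((grp["consequence"] == "synonymous").sum())
        lo, hi = proportion_confint(n, n + s, alpha=alpha, method="beta")
        row = dict(zip(group_cols, key))
        row.update({
            "n_nonsyn": n, "n_syn": s,
            "ratio": n / s if s else float("nan"),
            "ci_low": lo / (1 - lo) if lo < 1 else float("inf"),
            "ci_high": hi / (1 - hi) if hi < 1 else float("inf"),
            "undefined": s == 0,
        })
        rows.append(row)
    return pd.DataFrame(rows)
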