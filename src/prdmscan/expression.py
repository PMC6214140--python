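"""Paired tumor-normal differential expression and qPCR relative expression.

The paired test is a sign-flip permutation test on per-pair log2 CPM
ratios r_i = log2(tumorCPM_i / normalCPM_i): under the null of no
tumor/normal difference the r_i are symmetric about zero, so flipping
their signs regenerates the null distribution of the paired t statistic
exactly.  All 2^n flips are enumerated when feasible; otherwise Monte
Carlo with the add-one estimator.  Calls use the conventional paired-DE
thresholds |logFC| >= 1 and BH FDR <= 0.01.

qPCR relative expression follows the comparative-Ct method:
2^-ddCt with ddCt = (Ct_target - Ct_ref)_tumor - (Ct_target - Ct_ref)_normal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainInputError, NormalizationError, ValidationError


@dataclass(frozen=True)
class PairedCounts:
    """Gene x pair tumor and normal read-count matrices."""

    genes: tuple[str, ...]
    pairs: tuple[str, ...]
    tumor: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "pairs", tuple(self.pairs))
        shape = (len(self.genes), len(self.pairs))
        for name in ("tumor", "normal"):
            m = np.asarray(getattr(self, name))
            if m.shape != shape:
                raise ValidationError(
                    f"{name} matrix shape {m.shape} != (genes, pairs) {shape}"
                )
            if (m < 0).any():
                raise ValidationError(f"{name} matrix contains negative counts")
            object.__setattr__(self, name, m)

    def swapped(self) -> "PairedCounts":
        return PairedCounts(self.genes, self.pairs, self.normal, self.tumor)


class DECall(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NS = "NS"


def cpm_normalize(
    counts: np.ndarray,
    pseudocount: float = 0.5,
    sample_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Counts-per-million with an additive pseudocount.

    cell = 1e6 * (count + pseudocount) / (library size + G * pseudocount),
    where G is the number of genes; the pseudocount keeps log-ratios
    finite at zero counts.
    """
    counts = np.asarray(counts, dtype=float)
    colsums = counts.sum(axis=0)
    if (colsums <= 0).any():
        bad = int(np.argmax(colsums <= 0))
        name = sample_names[bad] if sample_names else f"column {bad}"
        raise NormalizationError(f"all-zero library: {name}")
    G = counts.shape[0]
    return 1e6 * (counts + pseudocount) / (colsums + G * pseudocount)


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ddct(
    ct_target_tumor: float,
    ct_ref_tumor: float,
    ct_target_normal: float,
    ct_ref_normal: float,
) -> float:
    """Relative expression 2^-ddCt of target vs reference, tumor vs normal."""
    cts = (ct_target_tumor, ct_ref_tumor, ct_target_normal, ct_ref_normal)
    if not all(math.isfinite(c) for c in cts):
        raise ValidationError(
            f"all Ct values must be finite (undetectable amplification), got {cts}"
        )
    delta_delta = (ct_target_tumor - ct_ref_tumor) - (ct_target_normal - ct_ref_normal)
    return 2.0 ** (-delta_delta)


@dataclass(frozen=True)
class QpcrMeasurement:
    ct_target_tumor: float
    ct_ref_tumor: float
    ct_target_normal: float
    ct_ref_normal: float
    relative_expression: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "relative_expression",
            ddct(self.ct_target_tumor, self.ct_ref_tumor,
                 self.ct_target_normal, self.ct_ref_normal),
        )


def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign vectors (+-1), identity (all +1) in row 0."""
    m = 1 << n
    bits = (np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1
    return 1.0 - 2.0 * bits


def paired_de(
    paired: PairedCounts,
    n_permutations: int = 10_000,
    seed: int | None = None,
    pseudocount: float = 0.5,
    logfc_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Sign-flip paired differential expression test, gene by gene.

    Returns a DataFrame with logFC (mean per-pair log2 CPM ratio), fold
    change 2^logFC, two-sided permutation p (doubled smaller tail, capped
    at 1), BH FDR, the UP/DOWN/NS call, and a flag for genes whose
    per-pair ratios have zero variance (reported with p = 1).
    """
    n = len(paired.pairs)
    if n < 3:
        raise DomainInputError(f"paired DE requires >= 3 pairs, got {n}")
    cpm_t = cpm_normalize(paired.tumor, pseudocount)
    cpm_n = cpm_normalize(paired.normal, pseudocount)
    r = np.log2(cpm_t / cpm_n)                        # genes x pairs
    G = r.shape[0]
    logfc = r.mean(axis=1)
    sd = r.std(axis=1, ddof=1)
    zero_var = sd == 0.0
    ss = (r ** 2).sum(axis=1)

    exact = (1 << n) <= n_permutations
    if exact:
        S = _sign_matrix(n)                           # 2^n x n
    else:
        rng = np.random.default_rng(seed)
        S = 1.0 - 2.0 * rng.integers(0, 2, size=(n_permutations, n)).astype(float)
    m = (S @ r.T) / n                                 # flips x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ss[None, :] - n * m ** 2) / (n - 1)
        var = np.maximum(var, 0.0)
        t_null = m / np.sqrt(var / n)
    t_null = np.where(np.isnan(t_null), 0.0, t_null)  # 0/0 -> no evidence

    p = np.ones(G)
    for g in range(G):
        if zero_var[g]:
            continue
        col = t_null[:, g]
        t_obs = col[0] if exact else logfc[g] / (sd[g] / math.sqrt(n))
        if exact:
            upper = float((col >= t_obs).mean())
            lower = float((col <= t_obs).mean())
        else:
            upper = (1 + int((col >= t_obs).sum())) / (1 + len(col))
            lower = (1 + int((col <= t_obs).sum())) / (1 + len(col))
        p[g] = min(1.0, 2.0 * min(upper, lower))

    fdr = bh_fdr(p)
    calls = np.where(
        (logfc >= logfc_threshold) & (fdr <= fdr_threshold), DECall.UP.value,
        np.where(
            (logfc <= -logfc_threshold) & (fdr <= fdr_threshold),
            DECall.DOWN.value, DECall.NS.value,
        ),
    )
    return pd.DataFrame({
        "gene_symbol": list(paired.genes),
        "logFC": logfc,
        "fold_change": 2.0 ** logfc,
        "p_value": p,
        "fdr": fdr,
        "call": calls,
        "zero_variance": zero_var,
    })


def read_paired_counts(path_tumor, path_normal) -> PairedCounts:
    """Read tumor and normal genes x pairs count TSVs (gene_symbol index)."""
    t = pd.read_csv(path_tumor, sep="\t", index_col=0)
    n = pd.read_csv(path_normal, sep="\t", index_col=0)
    if list(t.index) != list(n.index) or list(t.columns) != list(n.columns):
        raise ValidationError("tumor and normal count tables must align")
    return PairedCounts(
        tuple(t.index), tuple(t.columns),
        t.to_numpy(dtype=np.int64), n.to_numpy(dtype=np.int64),
    )


def write_paired_counts(paired: PairedCounts, path_tumor, path_normal) -> None:
    pd.DataFrame(paired.tumor, index=list(paired.genes),
                 columns=list(paired.pairs)).rename_axis("gene_symbol").to_csv(
        path_tumor, sep="\t")
    pd.DataFrame(paired.normal, index=list(paired.genes),
                 columns=list(paired.pairs)).rename_axis("gene_symbol").to_csv(
        path_normal, sep="\t")
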