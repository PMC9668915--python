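"""Label-free proteomics comparisons.

An LFQ table holds positive protein intensities per replicate (missing
values are NaN, never zero) with exactly two replicate groups.  The
analyses mirror a standard two-group label-free workflow: replicate
presence/absence intersection, dynamic-range ranking against a reference
protein list, a Welch-t permutation-FDR differential test with a linear
fold-change cutoff, and z-scored hierarchical clustering of the
significant proteins.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "LFQTable",
    "detect_common",
    "dynamic_range",
    "differential_test",
    "zscore_cluster",
]

# permutations are fully enumerated while the number of distinct splits
# (up to group swap) stays at or below this
_FULL_ENUMERATION_MAX = 1000


@dataclass
class LFQTable:
    """Protein x replicate intensities with a two-group design.

    ``data``: DataFrame indexed by protein identifier, one column per
    replicate, NaN marking absent values.  ``design`` maps each replicate
    column to its group label; exactly two groups, each with >= 2
    replicates.
    """

    data: pd.DataFrame
    design: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.design]
        if missing:
            raise ValueError(f"replicates without a group label: {missing}")
        groups = self.group_names
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, got {groups}")
        for g in groups:
            if len(self.columns_for(g)) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 replicates")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("present intensities must be positive")

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.data.columns:
            g = self.design[c]
            if g not in seen:
                seen.append(g)
        return seen

    def columns_for(self, group: str) -> list[str]:
        return [c for c in self.data.columns if self.design[c] == group]

    @classmethod
    def from_tsv(cls, table_path, design_path) -> "LFQTable":
        """Load intensities (first column = protein id) and a two-column
        replicate->group design file."""
        data = pd.read_csv(table_path, sep="\t", index_col=0)
        design_df = pd.read_csv(design_path, sep="\t")
        design = dict(zip(design_df.iloc[:, 0].astype(str),
                          design_df.iloc[:, 1].astype(str)))
        return cls(data=data, design=design)

    def to_tsv(self, table_path, design_path) -> None:
        self.data.to_csv(table_path, sep="\t", na_rep="NA")
        pd.DataFrame(
            {"replicate": list(self.data.columns),
             "group": [self.design[c] for c in self.data.columns]}
        ).to_csv(design_path, sep="\t", index=False)


def detect_common(table: LFQTable) -> dict:
    """Replicate presence intersection per group and the cross-group Venn.

    A protein is "common" in a group when present (non-missing) in every
    replicate of that group.  Returns per-replicate totals, per-group
    common sets and the intersection/unique split between the groups.
    """
    present = table.data.notna()
    g1, g2 = table.group_names
    per_replicate = {c: int(present[c].sum()) for c in table.data.columns}
    common: dict[str, set[str]] = {}
    detected: dict[str, set[str]] = {}
    for g in (g1, g2):
        cols = table.columns_for(g)
        common[g] = set(table.data.index[present[cols].all(axis=1)])
        detected[g] = set(table.data.index[present[cols].any(axis=1)])
    inter = common[g1] & common[g2]
    return {
        "groups": (g1, g2),
        "per_replicate": per_replicate,
        "n_detected": {g: len(detected[g]) for g in (g1, g2)},
        "n_common": {g: len(common[g]) for g in (g1, g2)},
        "common": {g: sorted(common[g]) for g in (g1, g2)},
        "n_intersection": len(inter),
        "n_unique": {g1: len(common[g1] - common[g2]),
                     g2: len(common[g2] - common[g1])},
        "intersection": sorted(inter),
    }


def dynamic_range(
    table: LFQTable,
    group: str | None = None,
    reference_list=(),
    top_k: int = 100,
) -> pd.DataFrame:
    """Rank proteins by median replicate intensity (descending).

    The median is taken over present values in the chosen group (first
    group by default); ties in the median break lexicographically by
    protein identifier.  The result carries the dynamic-range span in
    orders of magnitude and the number of reference proteins among the
    ``top_k`` most abundant in ``df.attrs``.
    """
    if group is None:
        group = table.group_names[0]
    cols = table.columns_for(group)
    if not cols:
        raise ValueError(f"no replicates in group {group!r}")
    med = table.data[cols].median(axis=1, skipna=True).dropna()
    if med.empty:
        raise ValueError("no protein has a present intensity in this group")
    ref = {str(p).casefold() for p in reference_list}
    df = pd.DataFrame({"protein": med.index.astype(str), "median_intensity": med.values})
    df = df.sort_values(
        ["median_intensity", "protein"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["log10_intensity"] = np.log10(df["median_intensity"])
    df["in_reference"] = df["protein"].str.casefold().isin(ref)
    df = df[["rank", "protein", "median_intensity", "log10_intensity", "in_reference"]]
    df.attrs["span_orders"] = float(
        df["log10_intensity"].max() - df["log10_intensity"].min()
    )
    df.attrs["n_reference_in_top_k"] = int(df["in_reference"].head(top_k).sum())
    df.attrs["top_k"] = top_k
    return df


def _masked_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    finite = np.isfinite(x)
    n = finite.sum(axis=1).astype(float)
    xz = np.where(finite, x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = xz.sum(axis=1) / n
        ss = np.where(finite, (x - m[:, None]) ** 2, 0.0).sum(axis=1)
        v = ss / (n - 1)  # NaN when n < 2, by construction
    return n, m, v


def _welch_t(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Row-wise Welch t on log-intensity matrices with NaN missingness.

    Rows with fewer than two present values in either group yield NaN
    (callers filter observed rows; permutation rows are dropped from the
    null pool)."""
    n1, m1, v1 = _masked_moments(x1)
    n2, m2, v2 = _masked_moments(x2)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(v1 / n1 + v2 / n2)
        t = (m1 - m2) / se
    # identical replicate values in both groups: no evidence either way
    t[np.isnan(t) & (np.abs(m1 - m2) < 1e-300) & (n1 >= 2) & (n2 >= 2)] = 0.0
    return t


def _distinct_splits(n1: int, n2: int) -> list[tuple[int, ...]]:
    """All splits of n1+n2 columns into groups of sizes n1/n2, up to group
    swap when the sizes are equal (|t| is swap-invariant)."""
    idx = range(n1 + n2)
    splits = [tuple(c) for c in itertools.combinations(idx, n1)]
    if n1 == n2:
        splits = [s for s in splits if 0 in s]
    return splits


def differential_test(
    table: LFQTable,
    fc_cutoff: float = 2.0,
    fdr_level: float = 0.05,
    n_perm: int = 250,
    seed: int = 0,
    min_valid: int = 2,
    log2_fc_cutoff: bool = False,
    exclude_observed: bool = True,
) -> pd.DataFrame:
    """Two-group Welch-t differential test with permutation FDR.

    Intensities are log2-transformed; proteins with fewer than
    ``min_valid`` present values in either group are dropped.  The null
    distribution of |t| comes from group-label permutations: all distinct
    splits (up to group swap) when there are at most 1,000, otherwise
    ``n_perm`` random splits drawn with ``seed``.  The observed labeling
    is excluded from the null by default.  For each threshold t = |t_i|,

        FDR(t) = mean over permutations of #{p : |t_perm,p| >= t}
                 / #{p : |t_obs,p| >= t},

    clipped to [0, 1] and made monotone non-increasing in t.  A protein
    is significant when q <= ``fdr_level`` and its linear fold change is
    at least ``fc_cutoff`` in either direction (with ``log2_fc_cutoff``
    the cutoff applies to |log2 FC| instead).

    Returns a DataFrame indexed by protein with columns ``mean_g1``,
    ``mean_g2`` (log2), ``log2_fc``, ``signed_fc``, ``t``, ``q``,
    ``significant``.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    g1, g2 = table.group_names
    c1, c2 = table.columns_for(g1), table.columns_for(g2)
    x = np.log2(table.data[c1 + c2].to_numpy(dtype=float))
    n1, n2 = len(c1), len(c2)
    valid = (np.sum(np.isfinite(x[:, :n1]), axis=1) >= min_valid) & (
        np.sum(np.isfinite(x[:, n1:]), axis=1) >= min_valid
    )
    proteins = table.data.index[valid]
    x = x[valid]
    if x.shape[0] == 0:
        raise ValueError("no protein passes the min_valid filter")

    t_obs = _welch_t(x[:, :n1], x[:, n1:])
    abs_t = np.abs(t_obs)

    observed = tuple(range(n1))
    splits = _distinct_splits(n1, n2)
    if exclude_observed:
        splits = [s for s in splits if s != observed]
    if len(splits) > _FULL_ENUMERATION_MAX:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(splits), size=min(n_perm, len(splits)), replace=False)
        splits = [splits[i] for i in sorted(pick)]
    if not splits:
        raise ValueError("no label permutations available for the null")

    perm_abs = []
    for s in splits:
        a = list(s)
        b = [i for i in range(n1 + n2) if i not in s]
        perm_abs.append(np.abs(_welch_t(x[:, a], x[:, b])))
    perm_pool = np.concatenate(perm_abs)
    # splits can leave a protein with < 2 present values in a permuted
    # group (NaN t): such entries carry no null information and are
    # dropped from the pool rather than counted at every threshold
    perm_pool = np.sort(perm_pool[np.isfinite(perm_pool)])
    n_splits = len(splits)

    order = np.argsort(-abs_t, kind="stable")  # descending |t|
    fdr = np.empty(x.shape[0])
    for rank, i in enumerate(order):
        t = abs_t[i]
        if not np.isfinite(t):
            fdr[i] = 0.0
            continue
        n_obs_ge = int(np.sum(abs_t >= t))
        n_perm_ge = perm_pool.size - int(np.searchsorted(perm_pool, t, side="left"))
        fdr[i] = min(1.0, (n_perm_ge / n_splits) / n_obs_ge)
    # enforce q monotone non-increasing in |t|: each protein gets the
    # minimum FDR over all thresholds at or below its own |t|
    q = np.empty_like(fdr)
    running = math.inf
    for i in order[::-1]:  # ascending |t|
        running = min(running, fdr[i])
        q[i] = running

    m1 = np.nanmean(x[:, :n1], axis=1)
    m2 = np.nanmean(x[:, n1:], axis=1)
    log2_fc = m1 - m2
    ratio = np.exp2(log2_fc)
    signed_fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    if log2_fc_cutoff:
        passes_fc = np.abs(log2_fc) >= fc_cutoff
    else:
        passes_fc = np.abs(signed_fc) >= fc_cutoff
    significant = (q <= fdr_level) & passes_fc

    return pd.DataFrame(
        {
            "mean_g1": m1,
            "mean_g2": m2,
            "log2_fc": log2_fc,
            "signed_fc": signed_fc,
            "t": t_obs,
            "q": q,
            "significant": significant,
        },
        index=pd.Index(proteins, name="protein"),
    )


def zscore_cluster(
    table: LFQTable,
    proteins=None,
    sd_mode: str = "sample",
) -> dict:
    """Row-wise z-scoring and average-linkage hierarchical clustering.

    Each protein row is z-scored across its present replicate values
    (``sd_mode`` selects sample (ddof=1) or population (ddof=0) standard
    deviation); rows with zero standard deviation are flagged and placed
    last.  Clustering is agglomerative with Euclidean distance and
    average linkage (missing z-scores treated as 0, the row mean, for
    distance purposes).  Returns the z-matrix, the scipy linkage and the
    deterministic leaf order.
    """
    data = table.data if proteins is None else table.data.loc[list(proteins)]
    if data.shape[0] < 2:
        raise ValueError("clustering needs at least 2 proteins")
    ddof = {"sample": 1, "population": 0}[sd_mode]
    x = np.log2(data.to_numpy(dtype=float))
    mean = np.nanmean(x, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(x, axis=1, ddof=ddof, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if constant.all():
        raise ValueError("every row is constant; nothing to cluster")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[constant] = np.nan

    usable = np.flatnonzero(~constant)
    zc = np.nan_to_num(z[usable], nan=0.0)
    lk = linkage(zc, method="average", metric="euclidean")
    leaf_order = [int(usable[i]) for i in leaves_list(lk)]
    leaf_order += [int(i) for i in np.flatnonzero(constant)]
    zdf = pd.DataFrame(z, index=data.index, columns=data.columns)
    return {
        "z": zdf,
        "linkage": lk,
        "leaf_order": [str(data.index[i]) for i in leaf_order],
        "constant_rows": [str(data.index[i]) for i in np.flatnonzero(constant)],
    }
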