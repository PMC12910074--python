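"""IZ-centric descriptive statistics.

Covers the signal summaries used downstream of IZ calling: per-IZ S-phase
time courses on a log2(x+1) scale, local-background-subtracted central
signal for chromatin-mark comparisons, rank-sum tests between groups,
nearest-feature distances (TSS / TTS / enhancers), and transcript decile
stratification with fraction-by-decile occupancy.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage, leaves_list
from statsmodels.stats.multitest import multipletests

from .core import BinnedTrack, PointFeatureSet
from .iz_calling import IZSet

#: distance reported when a query chromosome carries no feature of the kind
NO_FEATURE = np.nan


def iz_timecourse(timecourse: dict[float, BinnedTrack], izs: IZSet
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2(center-bin BPM + 1) per IZ per time point, plus per-class medians.

    Returns ``(values, medians)``: values has one row per IZ with columns
    ``rt_class`` and one column per time point; medians is indexed by
    (rt_class, time).
    """
    times = sorted(timecourse)
    data = {"rt_class": izs.df["rt_class"].to_numpy()}
    for t in times:
        track = timecourse[t]
        vals = [track.value_at(r.chrom, int(r.center))
                for r in izs.df.itertuples(index=False)]
        data[t] = np.log2(np.asarray(vals) + 1.0)
    values = pd.DataFrame(data)
    medians = values.groupby("rt_class")[times].median()
    medians = medians.stack().rename("median").reset_index()
    medians.columns = ["rt_class", "time_h", "median"]
    return values, medians


def local_background_central_signal(track: BinnedTrack, centers, plot_flank: int = 500_000,
                                    edge: int = 100_000, center_bin: int = 1000
                                    ) -> np.ndarray:
    """Central 1 kb-bin signal minus the mean of the outer ``edge`` bp of the
    plotted window on each side; one value per center.

    Invariant under adding any constant to the track. Windows that do not fit
    in the chromosome are dropped (NaN) with a warning.
    """
    if plot_flank <= edge:
        raise ValueError("plot_flank must exceed edge")
    bs = track.bin_size
    if center_bin != bs:
        raise ValueError("center_bin must equal the track bin size")
    n_flank = plot_flank // bs
    n_edge = edge // bs
    pairs = _center_pairs(centers)
    out = np.full(len(pairs), np.nan)
    for i, (chrom, pos) in enumerate(pairs):
        arr = track.data[chrom]
        c = int(pos) // bs
        if c - n_flank < 0 or c + n_flank >= len(arr):
            warnings.warn(f"window around {chrom}:{pos} exceeds chromosome; dropped")
            continue
        window = arr[c - n_flank: c + n_flank + 1]
        edges = np.concatenate([window[:n_edge], window[-n_edge:]])
        out[i] = window[n_flank] - edges.mean()
    return out


def _center_pairs(centers):
    if isinstance(centers, IZSet):
        return [(r.chrom, int(r.center)) for r in centers.df.itertuples(index=False)]
    if isinstance(centers, PointFeatureSet):
        return [(r.chrom, int(r.pos)) for r in centers.df.itertuples(index=False)]
    return [(c, int(p)) for c, p in centers]


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for small tie-free samples; mid-rank ties with a
    normal approximation and continuity correction otherwise. Two identical
    constant groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = a.size * b.size / 2.0
        return u, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size <= 20 and b.size <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def nearest_feature_distances(queries, features: PointFeatureSet) -> pd.DataFrame:
    """|query center - nearest feature| per query, per feature kind.

    ``queries`` is an IZSet or PointFeatureSet. Queries on chromosomes with no
    feature of a kind get NaN with a warning. Returns a frame with columns
    chrom, pos, rt_class (if available) and one distance column per kind.
    """
    pairs = _center_pairs(queries)
    out = pd.DataFrame(pairs, columns=["chrom", "pos"])
    if isinstance(queries, IZSet):
        out["rt_class"] = queries.df["rt_class"].to_numpy()
    for kind, grp in features.df.groupby("kind", sort=False):
        col = np.full(len(pairs), np.nan)
        by_chrom = {c: np.sort(g["pos"].to_numpy(np.int64))
                    for c, g in grp.groupby("chrom")}
        warned = set()
        for i, (chrom, pos) in enumerate(pairs):
            positions = by_chrom.get(chrom)
            if positions is None or positions.size == 0:
                if chrom not in warned:
                    warnings.warn(f"no {kind} features on {chrom}")
                    warned.add(chrom)
                continue
            j = np.searchsorted(positions, pos)
            cands = []
            if j < positions.size:
                cands.append(positions[j] - pos)
            if j > 0:
                cands.append(pos - positions[j - 1])
            col[i] = min(cands)
        out[f"dist_{kind}"] = col
    return out


def stratify_deciles(tpm_values) -> np.ndarray:
    """Decile label (1..10) per transcript, ranked by TPM.

    Rank-based: transcripts are stably sorted by TPM (ties keep input order)
    and decile = rank // ceil(n/10) + 1.
    """
    tpm = np.asarray(tpm_values, dtype=float)
    n = tpm.size
    if n < 10:
        raise ValueError("need at least 10 transcripts for deciles")
    if (tpm < 0).any():
        raise ValueError("TPM values must be >= 0")
    order = np.argsort(tpm, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks // math.ceil(n / 10) + 1).astype(np.int64)


def decile_occupancy(tpm_table: pd.DataFrame, reference: str | None = None,
                     linkage_method: str = "average") -> dict:
    """Fraction x decile occupancy matrix with hierarchical column clustering.

    ``tpm_table``: rows = transcripts, columns = sorted fractions. Deciles are
    assigned on the reference column (default: the mean across fractions);
    occupancy[f, d] counts transcripts detected (TPM > 0) in fraction f that
    fall in decile d, so each row sums to the fraction's detected-transcript
    count. Columns (deciles) are clustered by Euclidean distance with the
    given linkage (recorded in the output metadata).
    """
    ref = tpm_table[reference] if reference else tpm_table.mean(axis=1)
    deciles = stratify_deciles(ref.to_numpy())
    mat = np.zeros((tpm_table.shape[1], 10), dtype=np.int64)
    for fi, frac in enumerate(tpm_table.columns):
        detected = tpm_table[frac].to_numpy() > 0
        for d in range(1, 11):
            mat[fi, d - 1] = int(np.sum(detected & (deciles == d)))
    occupancy = pd.DataFrame(mat, index=tpm_table.columns,
                             columns=[f"decile_{d}" for d in range(1, 11)])
    Z = linkage(occupancy.T.to_numpy(), method=linkage_method, metric="euclidean")
    order = leaves_list(Z)
    return {"occupancy": occupancy, "deciles": deciles, "linkage": Z,
            "column_order": [occupancy.columns[i] for i in order],
            "metadata": {"linkage_method": linkage_method, "metric": "euclidean",
                         "reference": reference or "mean"}}


def quantile_ttests(tpm_a: pd.DataFrame, tpm_b: pd.DataFrame,
                    n_quantiles: int = 10) -> pd.DataFrame:
    """Per-quantile two-sided unpaired t-tests between two conditions with
    Benjamini-Hochberg correction across quantiles.

    Quantiles are assigned per condition on its own TPM ranking; quantile q of
    condition A is compared with quantile q of condition B.
    """
    qa = stratify_deciles(tpm_a.mean(axis=1).to_numpy())
    qb = stratify_deciles(tpm_b.mean(axis=1).to_numpy())
    rows = []
    for q in range(1, n_quantiles + 1):
        va = tpm_a.mean(axis=1).to_numpy()[qa == q]
        vb = tpm_b.mean(axis=1).to_numpy()[qb == q]
        t, p = sps.ttest_ind(va, vb, equal_var=False)
        rows.append((q, float(t), float(p)))
    df = pd.DataFrame(rows, columns=["quantile", "t_statistic", "p_value"])
    df["p_fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
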