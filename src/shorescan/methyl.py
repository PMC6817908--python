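"""Ordered-CpG promoter methylation analysis.

A promoter is modelled as an ordered run of Infinium-style CpG probes
spanning a north shore, a CpG island and a south shore.  Tumor-restricted
shore hypomethylation shows up as a rising segment of the cumulative
difference curve: the running sum, in probe order, of the per-CpG
difference in mean percent methylation (normal minus tumor).  A region of
consistent hypomethylation is a maximal run of consecutive probes that are
each both biologically (delta >= min_delta_pp) and statistically
(BH q <= q_max) hypomethylated, of at least ``min_run`` probes — the
operational version of the "steep slope" of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._util import bh_adjust

REGION_LABELS = ("north_shore", "island", "south_shore")


class CpGMap:
    """Ordered promoter CpG probes with region labels.

    Wraps a DataFrame indexed by probe id with columns ``chrom``, ``pos``
    (0-based) and ``region``.  Probes are kept in position order; region
    labels must form contiguous blocks in the order
    north_shore -> island -> south_shore (a block may be absent).
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        required = {"chrom", "pos", "region"}
        if not required.issubset(df.columns):
            raise ValueError(f"CpG map needs columns {sorted(required)}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate probe id {dup!r} in CpG map")
        unknown = set(df["region"]) - set(REGION_LABELS)
        if unknown:
            raise ValueError(f"unknown region label(s) {sorted(unknown)}")
        df = df.sort_values(["chrom", "pos"], kind="stable")
        for _, sub in df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("probe positions must be strictly increasing within chromosome")
        order = [REGION_LABELS.index(r) for r in df["region"]]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("region labels must run north_shore -> island -> south_shore")
        self.frame = df

    @property
    def probe_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def region_of(self, probe_id: str) -> str:
        return self.frame.loc[probe_id, "region"]

    def probes_in_region(self, region: str) -> list[str]:
        return list(self.frame.index[self.frame["region"] == region])

    def interval_probes(self, start_probe: str, end_probe: str) -> list[str]:
        """Probe ids between two probes of the map, inclusive, in map order."""
        ids = self.probe_ids
        try:
            i, j = ids.index(start_probe), ids.index(end_probe)
        except ValueError as exc:
            raise KeyError(f"interval endpoint not in CpG map: {exc}") from None
        if i > j:
            i, j = j, i
        return ids[i : j + 1]

    def to_bed_frame(self) -> pd.DataFrame:
        """BED-like table: chrom, start, end (=start+1), probe_id, region."""
        df = self.frame
        return pd.DataFrame(
            {
                "chrom": df["chrom"].to_numpy(),
                "start": df["pos"].to_numpy(),
                "end": df["pos"].to_numpy() + 1,
                "probe_id": df.index.to_numpy(),
                "region": df["region"].to_numpy(),
            }
        )


def load_cpg_map(path) -> CpGMap:
    """Read a BED-like TSV (chrom, start, end, probe_id, region) into a CpGMap.

    Rows may arrive in any order; the map is normalized to position order.
    """
    bed = pd.read_csv(path, sep="\t")
    needed = {"chrom", "start", "probe_id", "region"}
    if not needed.issubset(bed.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)} (BED-like TSV)")
    frame = pd.DataFrame(
        {"chrom": bed["chrom"].to_numpy(), "pos": bed["start"].to_numpy(), "region": bed["region"].to_numpy()},
        index=pd.Index(bed["probe_id"], name="probe_id"),
    )
    return CpGMap(frame)


def write_cpg_map(cpg_map: CpGMap, path) -> None:
    cpg_map.to_bed_frame().to_csv(path, sep="\t", index=False)


class BetaMatrix:
    """Per-sample methylation beta values over the probes of a CpGMap.

    ``values`` is probes x samples with beta in [0,1] (NaN = missing);
    ``groups`` labels each sample ``tumor`` or ``normal``.
    """

    def __init__(self, values: pd.DataFrame, groups: pd.Series):
        groups = groups.reindex(values.columns)
        if groups.isna().any():
            raise ValueError("every sample column needs a group label")
        arr = values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
                raise ValueError("beta values must lie in [0,1]")
        self.values = values
        self.groups = groups

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)], self.groups)


def group_mean_profile(beta: BetaMatrix, cpg_map: CpGMap, min_coverage: float = 0.5) -> pd.DataFrame:
    """Per-probe mean percent methylation for each group.

    Missing values are excluded probe-wise; a probe covered in fewer than
    ``min_coverage`` of a group's samples is dropped and recorded in
    ``profile.attrs['excluded']``.
    """
    for g in ("tumor", "normal"):
        if not beta.samples_in(g):
            raise ValueError(f"group {g!r} has no samples")
    vals = beta.values.reindex(cpg_map.probe_ids)
    out = {}
    for g in ("normal", "tumor"):
        sub = vals[beta.samples_in(g)]
        out[f"mean_pct_{g}"] = sub.mean(axis=1, skipna=True) * 100.0
        out[f"n_{g}"] = sub.notna().sum(axis=1)
        out[f"cov_{g}"] = sub.notna().mean(axis=1)
    prof = pd.DataFrame(out)
    ok = (prof["cov_normal"] >= min_coverage) & (prof["cov_tumor"] >= min_coverage)
    excluded = list(prof.index[~ok])
    prof = prof.loc[ok].drop(columns=["cov_normal", "cov_tumor"])
    prof.attrs["excluded"] = excluded
    return prof


def cumulative_difference(profile: pd.DataFrame, cpg_map: CpGMap) -> pd.DataFrame:
    """Cumulative normal-minus-tumor methylation difference in map order.

    delta[i] = mean_pct_normal[i] - mean_pct_tumor[i] (percentage points);
    cumulative[i] = delta[0] + ... + delta[i].  Positive rising segments
    mark consistent tumor hypomethylation; an island with no group
    difference contributes a flat segment.
    """
    if len(profile) == 0:
        raise ValueError("profile covers no probes")
    in_map = [p for p in cpg_map.probe_ids if p in profile.index]
    if list(profile.index) != in_map:
        raise ValueError("profile probe order does not match the CpG map")
    delta = profile["mean_pct_normal"] - profile["mean_pct_tumor"]
    return pd.DataFrame(
        {
            "mean_pct_normal": profile["mean_pct_normal"],
            "mean_pct_tumor": profile["mean_pct_tumor"],
            "delta": delta,
            "cumulative": delta.cumsum(),
        }
    )


def per_cpg_test(beta: BetaMatrix, cpg_map: CpGMap | None = None) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per probe (tumor vs normal), BH-adjusted.

    Probes with fewer than two non-missing values in either group are
    flagged untested (NaN p) and excluded from the adjustment.
    """
    probes = cpg_map.probe_ids if cpg_map is not None else list(beta.values.index)
    tum = beta.values[beta.samples_in("tumor")].reindex(probes)
    nor = beta.values[beta.samples_in("normal")].reindex(probes)
    p = np.full(len(probes), np.nan)
    tested = np.zeros(len(probes), dtype=bool)
    for i in range(len(probes)):
        t = tum.iloc[i].dropna().to_numpy()
        n = nor.iloc[i].dropna().to_numpy()
        if len(t) < 2 or len(n) < 2:
            continue
        combined = np.concatenate([t, n])
        if np.all(combined == combined[0]):
            p[i] = 1.0
        else:
            p[i] = stats.mannwhitneyu(t, n, alternative="two-sided").pvalue
        tested[i] = True
    out = pd.DataFrame({"p": p, "q": bh_adjust(p), "tested": tested}, index=pd.Index(probes, name="probe_id"))
    return out


@dataclass
class RegionCall:
    """A maximal run of consecutive consistently hypomethylated CpGs."""

    start_index: int
    end_index: int
    probe_ids: list[str]
    mean_delta: float
    q_values: list[float]
    regions_spanned: list[str]

    @property
    def run_length(self) -> int:
        return self.end_index - self.start_index + 1


def detect_consistent_region(
    cumdiff: pd.DataFrame,
    qvalues: pd.Series,
    cpg_map: CpGMap,
    min_run: int = 5,
    min_delta_pp: float = 5.0,
    q_max: float = 0.05,
) -> list[RegionCall]:
    """Call maximal runs of probes with delta >= min_delta_pp and q <= q_max.

    Runs shorter than ``min_run`` are discarded; calls are non-overlapping
    and ordered by position.  A single failing probe splits a run.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if not cumdiff.index.equals(qvalues.index):
        raise ValueError("cumulative profile and q-values are not aligned")
    delta = cumdiff["delta"].to_numpy()
    q = qvalues.to_numpy(dtype=float)
    passing = (delta >= min_delta_pp) & ~np.isnan(q) & (q <= q_max)
    calls: list[RegionCall] = []
    i = 0
    n = len(passing)
    probe_ids = list(cumdiff.index)
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            ids = probe_ids[i : j + 1]
            calls.append(
                RegionCall(
                    start_index=i,
                    end_index=j,
                    probe_ids=ids,
                    mean_delta=float(delta[i : j + 1].mean()),
                    q_values=[float(x) for x in q[i : j + 1]],
                    regions_spanned=sorted({cpg_map.region_of(p) for p in ids}, key=REGION_LABELS.index),
                )
            )
        i = j + 1
    return calls


def classify_methylation(beta, threshold: float = 0.5):
    """Classify beta value(s) as methylated (beta >= threshold) or unmethylated.

    The boundary beta == threshold is assigned to the methylated class.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta values must lie in [0,1]")
    labels = np.where(arr >= threshold, "methylated", "unmethylated")
    if np.isscalar(beta) or arr.ndim == 0:
        return str(labels)
    if isinstance(beta, pd.Series):
        return pd.Series(labels, index=beta.index)
    return labels


@dataclass
class ClusteringResult:
    sample_ids: list[str]
    linkage: np.ndarray
    leaf_order: list[str] = field(default_factory=list)

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids)


def cluster_samples(beta: BetaMatrix) -> ClusteringResult:
    """Agglomerative clustering of samples on their beta vectors.

    Euclidean distance, average linkage; probes with any missing value are
    dropped before computing distances.  Leaf order follows scipy's
    deterministic dendrogram ordering (ties broken by input sample order).
    """
    vals = beta.values.dropna(axis=0, how="any")
    if beta.values.notna().sum(axis=0).eq(0).any():
        bad = beta.values.columns[beta.values.notna().sum(axis=0).eq(0)][0]
        raise ValueError(f"sample {bad!r} has no observed beta values")
    if vals.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    X = vals.to_numpy().T
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(Z)
    samples = list(vals.columns)
    return ClusteringResult(
        sample_ids=samples,
        linkage=Z,
        leaf_order=[samples[i] for i in order],
    )


def write_region_calls(calls: list[RegionCall], cpg_map: CpGMap, bed_path, stats_path) -> None:
    """Emit region calls as BED intervals plus a statistics TSV."""
    rows, stats_rows = [], []
    for k, call in enumerate(calls):
        sub = cpg_map.frame.loc[call.probe_ids]
        rows.append(
            {
                "chrom": sub["chrom"].iloc[0],
                "start": int(sub["pos"].min()),
                "end": int(sub["pos"].max()) + 1,
                "name": f"region_{k+1}",
            }
        )
        stats_rows.append(
            {
                "name": f"region_{k+1}",
                "start_probe": call.probe_ids[0],
                "end_probe": call.probe_ids[-1],
                "run_length": call.run_length,
                "mean_delta_pp": call.mean_delta,
                "max_q": max(call.q_values),
                "regions_spanned": ";".join(call.regions_spanned),
            }
        )
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(bed_path, sep="\t", index=False, header=False)
    pd.DataFrame(
        stats_rows,
        columns=["name", "start_probe", "end_probe", "run_length", "mean_delta_pp", "max_q", "regions_spanned"],
    ).to_csv(stats_path, sep="\t", index=False)
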