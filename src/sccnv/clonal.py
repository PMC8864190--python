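"""Clone identification from per-cell copy-number profiles.

Normal cells are recognized by the absence of sizeable CNV calls; the
remaining tumor cells are clustered on their segment-ratio tracks (segment
means expanded back to bins, optionally restricted to informative
chromosomes) with Ward linkage on Euclidean distances, following the
standard hclust/ward.D2 treatment of single-cell CNV heatmaps.  Consensus
per-clone copy-number profiles, per-sample clone fractions and
superset-based ancestry hints are derived from the assignment, and exported
in a table ready for fishplot-style visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import InvalidArgumentError
from .segment import CNProfile

logger = logging.getLogger(__name__)


@dataclass
class CloneAssignment:
    """Cluster labels per cell plus the linkage tree that produced them."""

    labels: dict[str, str]            # cell_id -> cluster label ("C1" largest)
    sample_labels: dict[str, str]     # cell_id -> sample of origin
    linkage_tree: np.ndarray          # scipy linkage matrix
    k: int

    def cells_in(self, label: str) -> list[str]:
        return [c for c, l in self.labels.items() if l == label]


@dataclass
class CloneSummary:
    """Consensus CN per clone, per-sample clone fractions, ancestry hints."""

    consensus_cn: pd.DataFrame        # clones x bins, integer CN
    counts: pd.DataFrame              # samples x clones, tumor-cell counts
    fractions: pd.DataFrame           # samples x clones, fractions (rows sum to 1)
    parent_hints: dict[str, str | None] = field(default_factory=dict)


def identify_normal_cells(cn_profiles: dict[str, CNProfile],
                          min_call_size: int = 3_000_000,
                          max_abnormal_fraction: float = 0.02) -> dict[str, bool]:
    """Flag cells without chromosome-scale copy-number alterations as normal.

    A cell is normal when it has no CNV call of at least ``min_call_size``
    bp and the fraction of non-baseline bins does not exceed
    ``max_abnormal_fraction``.
    """
    out = {}
    for cell_id, prof in cn_profiles.items():
        big = any(c.length >= min_call_size for c in prof.calls)
        abn = prof.abnormal_bin_mask().mean()
        out[cell_id] = bool((not big) and abn <= max_abnormal_fraction)
    return out


def cluster_clones(ratio_matrix: pd.DataFrame,
                   k: int,
                   restrict_bins: np.ndarray | None = None,
                   sample_labels: dict[str, str] | None = None
                   ) -> CloneAssignment:
    """Ward clustering of cells on per-bin segment ratios.

    ``ratio_matrix`` is cells x bins (rows indexed by cell_id).
    ``restrict_bins`` optionally selects a boolean mask or index array of
    columns (e.g. the chromosomes carrying clone-defining events).  Cluster
    labels are "C1", "C2", ... ordered by decreasing cluster size.
    """
    n_cells = ratio_matrix.shape[0]
    if k < 1 or k > n_cells:
        raise InvalidArgumentError(f"k={k} not in [1, {n_cells}]")
    X = ratio_matrix.to_numpy(dtype=float)
    if restrict_bins is not None:
        X = X[:, restrict_bins]
    if np.any(~np.isfinite(X)):
        raise InvalidArgumentError("ratio matrix contains non-finite values")
    Z = linkage(X, method="ward")  # Ward-2 on Euclidean distances
    raw = fcluster(Z, t=k, criterion="maxclust")
    # order labels by decreasing cluster size (ties: first appearance)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], int(np.argmax(raw == l))))
    rename = {old: f"C{i + 1}" for i, old in enumerate(order)}
    labels = {cell: rename[r] for cell, r in zip(ratio_matrix.index, raw)}
    return CloneAssignment(labels=labels,
                           sample_labels=sample_labels or {},
                           linkage_tree=Z, k=int(len(set(raw))))


def suggest_k(ratio_matrix: pd.DataFrame, k_range: range = range(2, 7),
              restrict_bins: np.ndarray | None = None) -> int:
    """Silhouette-based suggestion for the cluster count (never auto-applied)."""
    from scipy.spatial.distance import pdist, squareform

    X = ratio_matrix.to_numpy(dtype=float)
    if restrict_bins is not None:
        X = X[:, restrict_bins]
    D = squareform(pdist(X))
    Z = linkage(X, method="ward")
    best_k, best_s = min(k_range), -np.inf
    for k in k_range:
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(set(lab)) < 2:
            continue
        s = _mean_silhouette(D, lab)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    n = D.shape[0]
    vals = np.empty(n)
    for i in range(n):
        same = labels == labels[i]
        same[i] = False
        a = D[i, same].mean() if same.any() else 0.0
        b = min(D[i, labels == l].mean() for l in set(labels) if l != labels[i])
        vals[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(vals.mean())


def _median_cn_toward_baseline(values: np.ndarray, baseline: int = 2) -> int:
    """Integer median; half-integer ties resolve to the value closer to 2."""
    med = float(np.median(values))
    if med == int(med):
        return int(med)
    lo, hi = int(np.floor(med)), int(np.ceil(med))
    return lo if abs(lo - baseline) <= abs(hi - baseline) else hi


def clone_consensus(cn_profiles: dict[str, CNProfile],
                    assignment: CloneAssignment,
                    baseline: int = 2) -> CloneSummary:
    """Per-clone consensus CN, per-sample fractions and ancestry hints.

    Consensus CN per bin is the per-clone median (ties resolved toward the
    diploid baseline).  Fractions are computed over the clustered (tumor)
    cells of each sample.  Clone X is hinted as a descendant candidate of
    clone Y when X's abnormal-bin set strictly contains Y's, agreeing with Y
    on at least 95% of Y's abnormal bins (same direction).
    """
    clones = sorted(set(assignment.labels.values()))
    missing = [c for c in assignment.labels if c not in cn_profiles]
    if missing:
        raise InvalidArgumentError(f"no CN profile for cells {missing[:3]}...")

    consensus = {}
    for clone in clones:
        cells = assignment.cells_in(clone)
        if not cells:
            logger.warning("clone %s is empty; excluded", clone)
            continue
        mat = np.stack([cn_profiles[c].cn_per_bin for c in cells])
        consensus[clone] = np.array(
            [_median_cn_toward_baseline(mat[:, j], baseline)
             for j in range(mat.shape[1])], dtype=np.int64)
    any_cell = next(iter(cn_profiles.values()))
    bin_ids = any_cell.scheme.bin_ids()
    consensus_df = pd.DataFrame.from_dict(consensus, orient="index",
                                          columns=bin_ids)

    samples = sorted(set(assignment.sample_labels.values())) or ["sample"]
    counts = pd.DataFrame(0, index=samples, columns=clones, dtype=int)
    for cell, clone in assignment.labels.items():
        sample = assignment.sample_labels.get(cell, "sample")
        counts.loc[sample, clone] += 1
    fractions = counts.div(counts.sum(axis=1), axis=0).fillna(0.0)

    hints: dict[str, str | None] = {}
    for x in clones:
        best = None
        best_n = -1
        for y in clones:
            if x == y:
                continue
            if _is_superset(consensus[x], consensus[y], baseline):
                ny = int(np.sum(consensus[y] != baseline))
                if ny > best_n:
                    best, best_n = y, ny
        hints[x] = best
    return CloneSummary(consensus_cn=consensus_df, counts=counts,
                        fractions=fractions, parent_hints=hints)


def _is_superset(cn_x: np.ndarray, cn_y: np.ndarray, baseline: int,
                 min_agreement: float = 0.95) -> bool:
    """True when x's CNV set strictly contains y's: >=95% agreement on y's
    abnormal bins (same direction), plus a strictly larger abnormal burden
    so that noisy consensus boundaries cannot make two clones mutual
    ancestors."""
    abn_y = cn_y != baseline
    abn_x = cn_x != baseline
    if not abn_y.any():
        return abn_x.any()
    same_dir = np.sign(cn_x - baseline) == np.sign(cn_y - baseline)
    agree = np.mean(same_dir[abn_y] & abn_x[abn_y])
    return agree >= min_agreement and abn_x.sum() > abn_y.sum()


def export_fishplot_table(summary: CloneSummary,
                          sample_order: list[str]) -> pd.DataFrame:
    """Tidy (sample, clone, fraction, parent) table for fishplot renderers.

    Fractions within each sample sum to 1 over the clones.
    """
    for s in sample_order:
        if s not in summary.fractions.index:
            raise InvalidArgumentError(f"unknown sample {s!r}")
    rows = []
    for sample in sample_order:
        for clone in summary.fractions.columns:
            rows.append({
                "sample": sample,
                "clone": clone,
                "fraction": float(summary.fractions.loc[sample, clone]),
                "parent": summary.parent_hints.get(clone) or "",
            })
    return pd.DataFrame(rows, columns=["sample", "clone", "fraction", "parent"])
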