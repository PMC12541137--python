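"""Plant-marker replicate QC, MOTU filtering and diet-profile construction.

Each fecal sample is amplified in three technical PCR replicates for the
plant marker.  Replicate consistency is judged compositionally: replicates
are converted to within-PCR proportions, the *barycenter* of a sample is
the arithmetic mean of its replicate proportion vectors, and two kinds of
distance are computed — each replicate's distance to its own barycenter
("PCR distances") and all pairwise distances between barycenters ("sample
distances").  Under clean amplification PCR distances are small relative
to sample distances, so the 5th percentile of a normal fitted to the
log-transformed sample distances is used as an upper bound: replicates
whose PCR distance exceeds it are discarded as outliers.

Further discards: replicates with fewer than 1000 reads (poor
amplification) and replicates compositionally clustering with the negative
controls.  The clustering rule is a deterministic k-nearest-neighbour
surrogate for a visual graph-partitioning step: a replicate whose majority
of k nearest neighbours (over all replicate and control composition
vectors) are controls is discarded.  Samples left with fewer than two
replicates are dropped.

Read counts are then averaged across the surviving two or three
replicates (on proportion vectors, rescaled by the mean depth, so that
replicates carry equal weight regardless of depth; raw-count averaging is
available), MOTUs with < 95% best-match similarity are removed as likely
artifacts, and MOTUs never reaching 2.5% relative read abundance (RRA)
in any sample are dropped as sporadic.  RRA is recomputed after every
removal stage.

The default compositional distance is Bray-Curtis on proportions,
matching the dissimilarity used downstream in the ordination; Euclidean
distance on Hellinger-transformed proportions is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import norm

from .io_model import (DietProfile, MOTUCatalog, ReadCountTable,
                       ReplicateQCTable)

MIN_PLANT_READS = 1000      #: replicates below this depth are discarded
MIN_SIMILARITY = 95.0       #: percent best-match similarity to keep a MOTU
MIN_MAX_RRA = 0.025         #: a MOTU must reach this RRA in >=1 sample
QC_QUANTILE = 0.05          #: lower quantile of sample distances
DEFAULT_KNN = 5             #: k for the control-clustering surrogate


def _proportions(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / totals
    p[np.isnan(p)] = 0.0
    return p


def _distance(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """Row-wise distances between matching rows of ``a`` and ``b``."""
    if metric == "braycurtis":
        num = np.abs(a - b).sum(axis=1)
        den = (a + b).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = num / den
        return np.where(den > 0, d, 0.0)
    if metric == "hellinger":
        return np.linalg.norm(np.sqrt(a) - np.sqrt(b), axis=1)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class ReplicateDistances:
    """Per-replicate distances to the own-sample barycenter and the
    pairwise between-barycenter (sample) distances."""

    pcr: pd.DataFrame             # sample_id, replicate_index, distance
    sample_distances: np.ndarray  # condensed pairwise barycenter distances
    barycenters: pd.DataFrame     # sample_id x MOTU proportion matrix
    flagged: list[str]            # samples with <2 replicates


def replicate_distances(plant: ReadCountTable, metric: str = "braycurtis"
                        ) -> ReplicateDistances:
    """Compute PCR distances and sample distances for plant replicates.

    Samples with fewer than two replicates are flagged and excluded from
    the between-barycenter distances used for threshold estimation.
    """
    frame = plant.frame[(plant.frame["marker"] == "plant")
                        & (plant.frame["control_kind"] == "none")]
    motus = plant.motus
    props = _proportions(frame[motus].to_numpy(dtype=float))
    sample_ids = frame["sample_id"].to_numpy()
    order = np.argsort(sample_ids, kind="stable")
    props, sample_ids = props[order], sample_ids[order]
    reps = frame["replicate_index"].to_numpy()[order]

    uniq, start = np.unique(sample_ids, return_index=True)
    bary_rows, flagged, keep_mask = [], [], np.ones(len(uniq), bool)
    pcr_dist = np.empty(len(sample_ids))
    bounds = list(start) + [len(sample_ids)]
    for i, sid in enumerate(uniq):
        sl = slice(bounds[i], bounds[i + 1])
        block = props[sl]
        bary = block.mean(axis=0)
        bary_rows.append(bary)
        pcr_dist[sl] = _distance(block, np.broadcast_to(bary, block.shape),
                                 metric)
        if block.shape[0] < 2:
            flagged.append(str(sid))
            keep_mask[i] = False
    bary = np.array(bary_rows)
    est = bary[keep_mask]
    if metric == "braycurtis":
        sdist = pdist(est, metric="braycurtis") if len(est) > 1 else \
            np.empty(0)
    else:
        sdist = pdist(np.sqrt(est), metric="euclidean") if len(est) > 1 \
            else np.empty(0)
    pcr = pd.DataFrame({"sample_id": sample_ids, "replicate_index": reps,
                        "distance": pcr_dist})
    bframe = pd.DataFrame(bary, columns=motus)
    bframe.insert(0, "sample_id", uniq)
    return ReplicateDistances(pcr, np.asarray(sdist), bframe, flagged)


def qc_threshold(sample_distances: np.ndarray, min_n: int = 20
                 ) -> float:
    """5th-percentile threshold from a log-normal fit of sample distances.

    A normal is fitted (maximum likelihood) to ``log`` of the positive
    sample distances; the threshold is ``exp(mu + z_0.05 * sigma)``.  With
    all distances equal the fit is degenerate (sigma = 0) and the common
    value is returned.
    """
    d = np.asarray(sample_distances, dtype=float)
    d = d[d > 0]
    if len(d) < min_n:
        raise ValueError(
            f"only {len(d)} positive sample distances (minimum {min_n}); "
            "supply an explicit threshold instead")
    logs = np.log(d)
    mu, sigma = logs.mean(), logs.std(ddof=0)
    return float(np.exp(mu + norm.ppf(QC_QUANTILE) * sigma))


def filter_replicates(plant: ReadCountTable, threshold: float,
                      min_reads: int = MIN_PLANT_READS,
                      knn_k: int = DEFAULT_KNN,
                      metric: str = "braycurtis"
                      ) -> tuple[ReplicateQCTable, ReadCountTable]:
    """Apply the three replicate discard rules; drop samples with <2 kept.

    Order: depth (<``min_reads``) -> distance to barycenter (> threshold,
    barycenters recomputed over depth-passing replicates) -> control-like
    (majority of ``knn_k`` nearest compositional neighbours are controls).
    """
    frame = plant.frame
    motus = plant.motus
    is_plant = frame["marker"] == "plant"
    samples = frame[is_plant & (frame["control_kind"] == "none")].copy()
    controls = frame[is_plant & (frame["control_kind"] != "none")]

    counts = samples[motus].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    status = np.full(len(samples), "kept", dtype=object)
    dist_col = np.full(len(samples), np.nan)
    status[totals < min_reads] = "discarded_low_reads"

    # distance rule on depth-passing replicates
    ok = status == "kept"
    sub = ReadCountTable(samples.loc[ok])
    rd = replicate_distances(sub, metric=metric)
    key = pd.MultiIndex.from_frame(
        samples.loc[ok, ["sample_id", "replicate_index"]])
    dmap = pd.Series(rd.pcr["distance"].to_numpy(),
                     index=pd.MultiIndex.from_frame(
                         rd.pcr[["sample_id", "replicate_index"]]))
    dist_col[ok] = dmap.loc[key].to_numpy()
    too_far = ok & (dist_col > threshold)
    status[too_far] = "discarded_distance"

    # control-clustering surrogate
    ctrl_counts = controls[motus].to_numpy(dtype=float)
    ctrl_props = _proportions(ctrl_counts)
    ctrl_props = ctrl_props[ctrl_counts.sum(axis=1) > 0]
    ok = status == "kept"
    if len(ctrl_props) and ok.sum():
        rep_props = _proportions(counts[ok])
        pool = np.vstack([rep_props, ctrl_props])
        is_ctrl = np.r_[np.zeros(len(rep_props), bool),
                        np.ones(len(ctrl_props), bool)]
        if metric == "braycurtis":
            d = cdist(rep_props, pool, metric="braycurtis")
        else:
            d = cdist(np.sqrt(rep_props), np.sqrt(pool), metric="euclidean")
        np.fill_diagonal(d[:, :len(rep_props)], np.inf)  # not own point
        k = min(knn_k, pool.shape[0] - 1)
        nn = np.argpartition(d, k - 1, axis=1)[:, :k]
        ctrl_frac = is_ctrl[nn].mean(axis=1)
        control_like = np.zeros(len(samples), bool)
        control_like[np.flatnonzero(ok)] = ctrl_frac > 0.5
        status[control_like] = "discarded_control_like"

    report = pd.DataFrame({
        "sample_id": samples["sample_id"].to_numpy(),
        "replicate_index": samples["replicate_index"].to_numpy(),
        "status": status, "distance_to_barycenter": dist_col,
        "threshold_used": threshold})
    kept = samples.loc[status == "kept"]
    n_kept = kept.groupby("sample_id")["replicate_index"].size()
    good_samples = set(n_kept[n_kept >= 2].index)
    retained = kept[kept["sample_id"].isin(good_samples)]
    return (ReplicateQCTable(report),
            ReadCountTable(retained.reset_index(drop=True)))


def average_replicates(retained: ReadCountTable,
                       mode: str = "proportions") -> pd.DataFrame:
    """sample x MOTU table averaged across kept replicates.

    ``proportions`` (default): mean of within-replicate proportion vectors,
    rescaled by the mean depth so the result stays on a read-count scale.
    ``counts``: plain mean of raw counts (depth-weighted).
    """
    frame = retained.frame
    motus = retained.motus
    counts = frame[motus].to_numpy(dtype=float)
    sids = frame["sample_id"].to_numpy()
    out = []
    for sid in pd.unique(sids):
        block = counts[sids == sid]
        if mode == "proportions":
            avg = _proportions(block).mean(axis=0) * block.sum(axis=1).mean()
        elif mode == "counts":
            avg = block.mean(axis=0)
        else:
            raise ValueError(f"unknown averaging mode {mode!r}")
        out.append(avg)
    table = pd.DataFrame(out, columns=motus)
    table.insert(0, "sample_id", pd.unique(sids))
    return table


def motu_filters(averaged: pd.DataFrame, catalog: MOTUCatalog,
                 min_similarity: float = MIN_SIMILARITY,
                 min_max_rra: float = MIN_MAX_RRA) -> pd.DataFrame:
    """Similarity and sporadic-occurrence filters on the averaged table.

    MOTUs with best-match similarity < ``min_similarity`` (percent) go
    first; RRA is then recomputed and MOTUs whose maximum RRA across all
    samples falls below ``min_max_rra`` are dropped.  Rows reduced to zero
    total are removed.
    """
    motus = [c for c in averaged.columns if c != "sample_id"]
    cat = catalog.frame.set_index("motu_id")
    sim_ok = [m for m in motus
              if m in cat.index
              and float(cat.loc[m, "best_similarity"]) >= min_similarity]
    table = averaged[["sample_id"] + sim_ok]
    vals = table[sim_ok].to_numpy(dtype=float)
    rra = _proportions(vals)
    keep = rra.max(axis=0) >= min_max_rra if len(rra) else \
        np.zeros(len(sim_ok), bool)
    kept_cols = [m for m, k in zip(sim_ok, keep) if k]
    table = table[["sample_id"] + kept_cols]
    nz = table[kept_cols].to_numpy(dtype=float).sum(axis=1) > 0
    return table.loc[nz].reset_index(drop=True)


def to_rra(table: pd.DataFrame) -> DietProfile:
    """Convert a sample x taxon read table to relative read abundances.

    Zero-total rows are dropped (they cannot be normalized).
    """
    taxa = [c for c in table.columns if c != "sample_id"]
    vals = table[taxa].to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    keep = totals > 0
    rra = vals[keep] / totals[keep, None]
    out = pd.DataFrame(rra, columns=taxa)
    out.insert(0, "sample_id", table["sample_id"].to_numpy()[keep])
    return DietProfile(out)


def collapse_taxa(table: pd.DataFrame, catalog: MOTUCatalog,
                  rank: str = "family",
                  category_map: dict[str, str] | None = None,
                  fallback: str | None = None) -> pd.DataFrame:
    """Sum reads within a taxonomic rank or a named category map.

    ``rank`` may be 'family'/'genus'/'species' (taken from the catalog
    taxonomy) or 'category', in which case ``category_map`` (MOTU or taxon
    -> category) is required.  MOTUs with no mapping raise unless a
    ``fallback`` category such as 'other' is given.
    """
    motus = [c for c in table.columns if c != "sample_id"]
    if rank == "category":
        if category_map is None:
            raise ValueError("category collapsing requires category_map")
        mapping = {}
        unmapped = []
        for m in motus:
            if m in category_map:
                mapping[m] = category_map[m]
            elif fallback is not None:
                mapping[m] = fallback
            else:
                unmapped.append(m)
        if unmapped:
            raise ValueError("no category for MOTU(s): "
                             + ", ".join(unmapped))
    else:
        names = catalog.taxonomy_rank(rank)
        mapping = {m: names.get(m, fallback) for m in motus}
        missing = [m for m, v in mapping.items() if v is None]
        if missing:
            raise ValueError("no taxonomy for MOTU(s): "
                             + ", ".join(missing))
    groups: dict[str, list[str]] = {}
    for m in motus:
        groups.setdefault(mapping[m], []).append(m)
    out = pd.DataFrame({"sample_id": table["sample_id"].to_numpy()})
    for name in sorted(groups):
        out[name] = table[groups[name]].sum(axis=1).to_numpy()
    return out


def build_diet_profile(plant: ReadCountTable, catalog: MOTUCatalog,
                       threshold: float | None = None,
                       rank: str | None = None,
                       category_map: dict[str, str] | None = None,
                       min_reads: int = MIN_PLANT_READS,
                       knn_k: int = DEFAULT_KNN,
                       metric: str = "braycurtis",
                       min_similarity: float = MIN_SIMILARITY,
                       min_max_rra: float = MIN_MAX_RRA,
                       ) -> tuple[DietProfile, ReplicateQCTable,
                                  pd.DataFrame]:
    """Full plant pipeline: QC -> average -> MOTU filters -> (collapse) -> RRA.

    Returns the diet profile, the replicate QC report and the filtered
    sample x MOTU read table (pre-collapse), whose positive entries define
    per-sample diet richness.
    """
    if threshold is None:
        rd = replicate_distances(plant, metric=metric)
        threshold = qc_threshold(rd.sample_distances)
    report, retained = filter_replicates(plant, threshold,
                                         min_reads=min_reads, knn_k=knn_k,
                                         metric=metric)
    averaged = average_replicates(retained)
    filtered = motu_filters(averaged, catalog, min_similarity=min_similarity,
                            min_max_rra=min_max_rra)
    table = filtered
    if rank is not None:
        table = collapse_taxa(filtered, catalog, rank=rank,
                              category_map=category_map, fallback="other")
    return to_rra(table), report, filtered
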