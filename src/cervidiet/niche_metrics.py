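"""Diet richness, dietary niche width, overlap and selectivity statistics.

* Richness ``S``: number of taxa detected (RRA > 0) in a fecal sample,
  counted on the post-QC, pre-collapse MOTU table.  Between-species
  differences are tested with pairwise Dunn rank tests (mid-rank ties,
  tie-corrected variance, two-sided normal p) and Benjamini-Hochberg
  adjustment across pairs.
* Dietary niche width ``DNW = exp(H')``: the order-1 Hill number of the
  *average* diet of a landscape x species x season stratum, where the
  average diet is the unweighted arithmetic mean of the sample RRA
  vectors (renormalized).  1 <= DNW <= number of taxa, with equality to
  the taxon count only for a uniform average diet.
* Pianka's overlap ``O = sum(u_i v_i) / sqrt(sum(u_i^2) sum(v_i^2))``
  between two diet proportion vectors: 0 = no overlap, 1 = identical use.
  Intraspecific overlap on a transect is the mean Pianka over all
  unordered pairs of conspecific samples; interspecific overlap is the
  Pianka index between the two species' mean diets on that transect.
* Jacob's selectivity ``D = (r - p) / (r + p - 2 r p)`` contrasting the
  dietary proportion ``r`` of a food category with its environmental
  availability ``p`` in the species' browsing-height range; -1 = total
  avoidance, +1 = exclusive preference, 0 = neutral.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .io_model import (SPECIES_HEIGHT_RANGE, AvailabilityTable, DietProfile,
                       OverlapTable, SampleMetadata)


# ---------------------------------------------------------------------------
# Richness and Dunn tests

def richness(profile: DietProfile | pd.DataFrame,
             metadata: SampleMetadata | None = None,
             species: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample count of taxa with positive abundance.

    ``profile`` may be a DietProfile or any sample x taxon table with a
    ``sample_id`` column.  If ``metadata`` (and optionally a sample_id ->
    species mapping) is given, the stratifiers are joined on.
    """
    frame = profile.frame if isinstance(profile, DietProfile) else profile
    taxa = [c for c in frame.columns if c != "sample_id"]
    S = (frame[taxa].to_numpy() > 0).sum(axis=1)
    out = pd.DataFrame({"sample_id": frame["sample_id"].to_numpy(),
                        "S": S.astype(int)})
    if metadata is not None:
        meta = metadata.frame[["sample_id", "transect_id", "landscape",
                               "season"]]
        out = out.merge(meta, on="sample_id", how="left")
    if species is not None:
        out["species"] = out["sample_id"].map(species)
    return out


def dunn_bh(values, groups) -> pd.DataFrame:
    """Pairwise Dunn tests on pooled mid-ranks with BH adjustment.

    z = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)] with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)).  Groups with fewer
    than two observations are excluded (with a warning column implicit in
    their absence).  Two-sided p-values; BH step-up across all pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)
              if (groups == g).sum() >= 2]
    if len(labels) < 2:
        raise ValueError("need >=2 groups with >=2 observations")
    mask = np.isin(groups, labels)
    values, groups = values[mask], groups[mask]
    ranks = rankdata(values)  # mid-ranks
    N = len(values)
    _, counts = np.unique(values, return_counts=True)
    T = ((counts ** 3 - counts).sum()) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - T
    rows = []
    for a, b in itertools.combinations(labels, 2):
        ra, rb = ranks[groups == a], ranks[groups == b]
        se = math.sqrt(var_base * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
        p = 2.0 * norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Niche width

def shannon(q: np.ndarray) -> float:
    q = np.asarray(q, dtype=float)
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


def dnw(profiles: np.ndarray | pd.DataFrame) -> float:
    """Dietary niche width of a stratum: exp(H') of the mean sample diet."""
    if isinstance(profiles, pd.DataFrame):
        profiles = profiles[[c for c in profiles.columns
                             if c != "sample_id"]].to_numpy()
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[0] == 0:
        raise ValueError("empty stratum")
    avg = profiles.mean(axis=0)
    avg = avg / avg.sum()
    return float(np.exp(shannon(avg)))


def dnw_table(profile: DietProfile, metadata: SampleMetadata,
              species: pd.Series) -> pd.DataFrame:
    """Population-level DNW per landscape x species x season."""
    frame = profile.frame.merge(
        metadata.frame[["sample_id", "landscape", "season"]], on="sample_id")
    frame["species"] = frame["sample_id"].map(species)
    taxa = profile.taxa
    rows = []
    for (lsc, sea, sp), grp in frame.groupby(
            ["landscape", "season", "species"], sort=True):
        rows.append({"landscape": lsc, "season": sea, "species": sp,
                     "n_samples": len(grp), "dnw": dnw(grp[taxa].to_numpy())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Overlap

def pianka(u, v) -> float:
    """Pianka's niche overlap of two proportion vectors (in [0, 1])."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    su, sv = (u * u).sum(), (v * v).sum()
    if su == 0 or sv == 0:
        raise ValueError("Pianka's index is undefined for a zero vector")
    return float(np.clip((u * v).sum() / math.sqrt(su * sv), 0.0, 1.0))


def _pairwise_pianka_mean(mat: np.ndarray) -> float:
    """Mean Pianka over all unordered row pairs (vectorized)."""
    norms = np.linalg.norm(mat, axis=1)
    G = (mat @ mat.T) / np.outer(norms, norms)
    iu = np.triu_indices(len(mat), k=1)
    return float(np.clip(G[iu], 0.0, 1.0).mean())


def overlap_table(profile: DietProfile, metadata: SampleMetadata,
                  species: pd.Series, mode: str = "both",
                  inter_method: str = "mean_diet") -> OverlapTable:
    """Transect-scale intra- and interspecific Pianka overlap.

    intra: mean Pianka over all unordered conspecific sample pairs on a
    transect x season (needs >=2 samples).  inter: Pianka between the two
    species' mean diets on the transect (``mean_diet``, default) or the
    mean over heterospecific sample pairs (``pair_mean``).
    """
    frame = profile.frame.merge(
        metadata.frame[["sample_id", "transect_id", "landscape", "season"]],
        on="sample_id")
    frame["species"] = frame["sample_id"].map(species)
    taxa = profile.taxa
    rows = []
    for (tr, sea, lsc), grp in frame.groupby(
            ["transect_id", "season", "landscape"], sort=True):
        by_sp = {sp: g[taxa].to_numpy() for sp, g in grp.groupby("species")}
        if mode in ("both", "intra"):
            for sp, mat in sorted(by_sp.items()):
                if len(mat) >= 2:
                    rows.append({"transect_id": tr, "season": sea,
                                 "landscape": lsc, "kind": "intra",
                                 "species_a": sp, "species_b": sp,
                                 "pianka": _pairwise_pianka_mean(mat),
                                 "n_samples_a": len(mat),
                                 "n_samples_b": len(mat)})
        if mode in ("both", "inter"):
            for sa, sb in itertools.combinations(sorted(by_sp), 2):
                ma, mb = by_sp[sa], by_sp[sb]
                if inter_method == "mean_diet":
                    o = pianka(ma.mean(axis=0), mb.mean(axis=0))
                else:
                    norms_a = np.linalg.norm(ma, axis=1)
                    norms_b = np.linalg.norm(mb, axis=1)
                    G = (ma @ mb.T) / np.outer(norms_a, norms_b)
                    o = float(np.clip(G, 0.0, 1.0).mean())
                rows.append({"transect_id": tr, "season": sea,
                             "landscape": lsc, "kind": "inter",
                             "species_a": sa, "species_b": sb, "pianka": o,
                             "n_samples_a": len(ma), "n_samples_b": len(mb)})
    if not rows:
        return OverlapTable(pd.DataFrame(columns=OverlapTable.FIXED))
    return OverlapTable(pd.DataFrame(rows))


def overlap_summary(overlaps: OverlapTable, low_n: int = 4) -> pd.DataFrame:
    """Mean +- SD across transects per landscape x season x species (pair).

    Cells resting on fewer than ``low_n`` transects are flagged, mirroring
    the caution note attached to thinly replicated cells.
    """
    frame = overlaps.frame
    rows = []
    for key, grp in frame.groupby(
            ["landscape", "season", "kind", "species_a", "species_b"],
            sort=True):
        n = len(grp)
        rows.append({
            "landscape": key[0], "season": key[1], "kind": key[2],
            "species_a": key[3], "species_b": key[4],
            "mean_pianka": float(grp["pianka"].mean()),
            "sd_pianka": float(grp["pianka"].std(ddof=1)) if n > 1
            else float("nan"),
            "n_transects": n, "low_replication": n < low_n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Selectivity

def jacobs_d(r: float, p: float) -> float:
    """Jacob's selectivity index; NaN when undefined (r=p=0 or r=p=1)."""
    den = r + p - 2.0 * r * p
    if den == 0:
        return float("nan")
    return float((r - p) / den)


def selectivity_table(profile_by_category: DietProfile,
                      availability: AvailabilityTable,
                      metadata: SampleMetadata,
                      species: pd.Series) -> pd.DataFrame:
    """Jacob's D per transect x season x species x food category.

    ``r`` is the transect-average diet proportion of the category (over
    the species' samples on that transect and season), ``p`` the
    availability proportion in the species' browsing-height range.  A
    category present in the diet but missing from the availability survey
    is scored with p = 0 (D = 1 whenever r > 0).
    """
    frame = profile_by_category.frame.merge(
        metadata.frame[["sample_id", "transect_id", "landscape", "season"]],
        on="sample_id")
    frame["species"] = frame["sample_id"].map(species)
    cats = profile_by_category.taxa
    avail = availability.frame.set_index(
        ["transect_id", "season", "height_range", "category"])["proportion"]
    rows = []
    for (tr, sea, lsc, sp), grp in frame.groupby(
            ["transect_id", "season", "landscape", "species"], sort=True):
        hr = SPECIES_HEIGHT_RANGE[sp]
        mean_diet = grp[cats].to_numpy().mean(axis=0)
        for cat, r in zip(cats, mean_diet):
            p = float(avail.get((tr, sea, hr, cat), 0.0))
            if r == 0 and p == 0:
                continue
            rows.append({"transect_id": tr, "season": sea,
                         "landscape": lsc, "species": sp, "category": cat,
                         "r": float(r), "p": p, "D": jacobs_d(r, p),
                         "n_samples": len(grp)})
    return pd.DataFrame(rows)


def selectivity_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SD of transect-level D per landscape x season x species x
    category; single-transect strata are flagged (SD undefined)."""
    rows = []
    for key, grp in records.groupby(
            ["landscape", "season", "species", "category"], sort=True):
        n = len(grp)
        rows.append({
            "landscape": key[0], "season": key[1], "species": key[2],
            "category": key[3], "mean_D": float(grp["D"].mean()),
            "sd_D": float(grp["D"].std(ddof=1)) if n > 1 else float("nan"),
            "n_transects": n, "single_transect": n < 2})
    return pd.DataFrame(rows)
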