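"""Host (deer) species assignment from mammal-marker read counts.

A fecal sample's origin is confirmed from its single mammal-marker PCR:
within each PCR, MOTUs carrying less than 1% of the reads are removed
(they are dominated by artifacts), MOTUs shorter than 40 bp are removed
(mostly bacterial), and PCRs left with fewer than 500 reads are rejected
as poor amplifications.  The host is then the species of the most abundant
MOTU that exactly matches a reference sequence; when more than one mammal
species survives filtering, the dominant species' top MOTU must be at
least twice as abundant as the runner-up species' top MOTU, otherwise the
sample is discarded as ambiguous.

The 2x dominance rule compares the top MOTU of each detected species (not
species-aggregated read sums); "species detected" means any retained
exact-reference-match MOTU of that species.  A tie for the most abundant
MOTU is ambiguous by construction (the ratio cannot reach 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io_model import HostAssignmentTable, MOTUCatalog, ReadCountTable

MIN_SHARE = 0.01      #: within-PCR read share below which a MOTU is removed
MIN_LENGTH_BP = 40    #: MOTUs shorter than this are treated as artifacts
MIN_READS = 500       #: PCRs with fewer total reads (after filters) fail
DOMINANCE = 2.0       #: required top-species / second-species read ratio


@dataclass
class HostAssignment:
    sample_id: str
    status: str                      # assigned / discarded_*
    assigned_species: str = ""
    dominant_motu: str = ""
    dominance_ratio: float = float("nan")


def filter_mammal_pcr(counts: pd.Series, catalog: MOTUCatalog
                      ) -> pd.Series | None:
    """Apply the within-PCR mammal filters; ``None`` means the PCR failed.

    ``counts`` maps MOTU id -> reads for one mammal-marker PCR.  Removal
    order: <1% read share, then <40 bp; a PCR retaining <500 reads after
    both is rejected.  The share filter is scale-invariant by construction.
    """
    counts = counts[counts > 0]
    total = counts.sum()
    if total == 0:
        return None
    counts = counts[counts / total >= MIN_SHARE]
    cat = catalog.frame.set_index("motu_id")
    lengths = cat["length_bp"]
    keep = [m for m in counts.index
            if lengths.get(m, MIN_LENGTH_BP) >= MIN_LENGTH_BP]
    counts = counts[keep]
    if counts.sum() < MIN_READS:
        return None
    return counts


def assign_species(filtered: pd.Series, catalog: MOTUCatalog,
                   sample_id: str = "") -> HostAssignment:
    """Dominance-rule species call on a filtered mammal PCR."""
    cat = catalog.frame.set_index("motu_id")
    exact = [m for m in filtered.index
             if m in cat.index and bool(cat.loc[m, "is_reference_exact"])]
    if not exact:
        return HostAssignment(sample_id, "discarded_no_reference_match")
    species_of = {m: cat.loc[m, "taxonomy"].split(";")[-1] for m in exact}
    # top MOTU per detected species
    top: dict[str, tuple[str, int]] = {}
    for m in exact:
        sp = species_of[m]
        if sp not in top or filtered[m] > top[sp][1]:
            top[sp] = (m, int(filtered[m]))
    ranked = sorted(top.values(), key=lambda t: -t[1])
    dom_motu, dom_reads = ranked[0]
    if len(ranked) == 1:
        ratio = math.inf
    else:
        second = ranked[1][1]
        if dom_reads == second:
            return HostAssignment(sample_id, "discarded_ambiguous",
                                  dominant_motu=dom_motu,
                                  dominance_ratio=1.0)
        ratio = dom_reads / second
        if ratio < DOMINANCE:
            return HostAssignment(sample_id, "discarded_ambiguous",
                                  dominant_motu=dom_motu,
                                  dominance_ratio=ratio)
    return HostAssignment(sample_id, "assigned",
                          assigned_species=species_of[dom_motu],
                          dominant_motu=dom_motu, dominance_ratio=ratio)


def assign_hosts(read_counts: ReadCountTable, catalog: MOTUCatalog
                 ) -> HostAssignmentTable:
    """Run filter + dominance assignment for every mammal-marker sample PCR."""
    frame = read_counts.frame
    mam = frame[(frame["marker"] == "mammal")
                & (frame["control_kind"] == "none")]
    records = []
    for _, row in mam.iterrows():
        counts = row[read_counts.motus].astype(int)
        filtered = filter_mammal_pcr(counts, catalog)
        if filtered is None:
            rec = HostAssignment(row["sample_id"], "discarded_low_reads")
        else:
            rec = assign_species(filtered, catalog, row["sample_id"])
        records.append(rec)
    out = pd.DataFrame(
        [{"sample_id": r.sample_id, "status": r.status,
          "assigned_species": r.assigned_species,
          "dominant_motu": r.dominant_motu,
          "dominance_ratio": r.dominance_ratio} for r in records])
    if not len(out):
        out = pd.DataFrame(columns=HostAssignmentTable.FIXED)
    return HostAssignmentTable(out)
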