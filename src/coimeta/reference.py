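"""Reference-database curation, species assignment and OTU completeness profiling.

The reference database is a set of COI barcode records with species and
phylum labels (BOLD-style).  Curation removes terrestrial records, records
without a species-level name, and records on an explicit exclusion list
(the iterative multi-hit curation loop of a metabarcoding survey).
Assignment matches each merged insert to its best reference at >= 97%
identity; equal-best hits to more than one species are held out of the
community matrix and tallied for curation.  Reference completeness is
profiled by clustering inserts into OTUs at 97% similarity and asking what
fraction of OTUs sit within the species-assignable identity band.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import (ReferenceIndex, banded_distance, best_hits,
                    max_edit_distance, pairwise_identity)
from .matrix import CommunityMatrix

logger = logging.getLogger(__name__)

TERRESTRIAL_HABITATS = {"terrestrial"}


@dataclass
class ReferenceRecord:
    """One barcode record.  ``species_name`` is None for records that were
    never identified to species level (these are removed during curation)."""

    record_id: str
    species_name: str | None
    phylum: str
    sequence: str
    habitat: str | None = None
    flags: set = field(default_factory=set)


def _is_unnamed(name: str | None) -> bool:
    if name is None:
        return True
    name = name.strip()
    if not name or name.upper() in {"NA", "N/A"}:
        return True
    parts = name.split()
    # genus-only or open nomenclature ("Genus sp.") lacks a species epithet
    if len(parts) < 2:
        return True
    if parts[-1].rstrip(".").lower() in {"sp", "spp", "cf", "aff"}:
        return True
    return False


def parse_reference_fasta(path) -> list[ReferenceRecord]:
    """Read a reference FASTA with ``>record_id|species|phylum[|habitat]`` headers."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split("|")
        if len(fields) < 3:
            raise ValueError(
                f"malformed reference header (need record_id|species|phylum): {rec.description!r}"
            )
        rid, name, phylum = fields[0].strip(), fields[1].strip(), fields[2].strip()
        habitat = fields[3].strip().lower() if len(fields) > 3 else None
        records.append(
            ReferenceRecord(
                record_id=rid,
                species_name=None if _is_unnamed(name) else name,
                phylum=phylum,
                sequence=str(rec.seq).upper(),
                habitat=habitat,
            )
        )
    return records


def write_reference_fasta(records: list[ReferenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            name = rec.species_name if rec.species_name else "sp."
            header = f"{rec.record_id}|{name}|{rec.phylum}"
            if rec.habitat is not None:
                header += f"|{rec.habitat}"
            fh.write(f">{header}\n{rec.sequence}\n")


def curate_reference(
    raw_db: list[ReferenceRecord],
    exclusion_list: list[str] | set[str] = (),
    terrestrial_species: set[str] | None = None,
) -> tuple[list[ReferenceRecord], pd.DataFrame]:
    """Remove terrestrial, unnamed and explicitly excluded records.

    Terrestrial records are identified from the record's habitat annotation
    when present, otherwise from the caller-supplied ``terrestrial_species``
    set (the manual-curation route).  Returns the curated database and a
    log of every removal with its reason.
    """
    exclusion = {e.strip() for e in exclusion_list}
    terrestrial_species = terrestrial_species or set()
    known = {r.species_name for r in raw_db if r.species_name}
    for sp in exclusion - known:
        warnings.warn(f"exclusion-list species not in database: {sp}")

    curated: list[ReferenceRecord] = []
    log_rows = []
    for rec in raw_db:
        reason = None
        if _is_unnamed(rec.species_name):
            rec.flags.add("unnamed")
            reason = "unnamed"
        elif (rec.habitat in TERRESTRIAL_HABITATS) or (
            rec.species_name in terrestrial_species
        ):
            rec.flags.add("terrestrial")
            reason = "terrestrial"
        elif rec.species_name in exclusion:
            rec.flags.add("excluded_by_list")
            reason = "excluded_by_list"
        if reason is None:
            curated.append(rec)
        else:
            log_rows.append({"record_id": rec.record_id,
                             "species_name": rec.species_name or "",
                             "reason": reason})
    log = pd.DataFrame(log_rows, columns=["record_id", "species_name", "reason"])
    return curated, log


@dataclass
class HitSet:
    """Best-hit summary for one query insert."""

    query_id: str
    best_identity: float
    species_at_best: frozenset
    n_ref_records_at_best: int

    @property
    def is_multi_hit(self) -> bool:
        return len(self.species_at_best) > 1


@dataclass
class AssignmentResult:
    matrix: CommunityMatrix
    multi_hit_report: pd.DataFrame       # species_set, n_reads, n_cases
    tallies: pd.DataFrame                # per sample: assigned/multi_hit/unassigned
    hits: dict                           # unique sequence -> HitSet


def assign_reads(
    inserts: dict[str, "Counter[str] | list[str]"],
    db: list[ReferenceRecord],
    threshold: float = 0.97,
    metadata: pd.DataFrame | None = None,
    marker_id: str | None = None,
) -> AssignmentResult:
    """Direct taxonomic assignment of inserts at >= ``threshold`` identity.

    ``inserts`` maps sample_id to its insert sequences (list or Counter).
    Sequences are dereplicated across samples before alignment; each unique
    sequence is aligned once and its counts propagated.  Reads whose best
    identity ties across more than one species are *held out* of the matrix
    and tallied in the multi-hit report for reference curation.
    """
    if not db:
        raise ValueError("no references")
    if not 0.5 < threshold <= 1:
        raise ValueError("threshold must be in (0.5, 1]")

    refs = [(rec.species_name, rec.sequence) for rec in db]
    per_sample = {
        s: (seqs if isinstance(seqs, Counter) else Counter(seqs))
        for s, seqs in inserts.items()
    }
    unique = sorted(set().union(*[c.keys() for c in per_sample.values()]))

    index = ReferenceIndex(refs)
    hits: dict[str, HitSet] = {}
    for i, seq in enumerate(unique):
        ident, idx = best_hits(seq, refs, min_identity=threshold, index=index)
        species = frozenset(refs[j][0] for j in idx)
        hits[seq] = HitSet(f"u{i}", ident, species, len(idx))

    species_order = sorted({rec.species_name for rec in db})
    rows, tally_rows = [], []
    multi: Counter = Counter()
    multi_reads: Counter = Counter()
    for sample, counter in per_sample.items():
        counts = dict.fromkeys(species_order, 0)
        n_assigned = n_multi = n_unassigned = 0
        for seq, n in counter.items():
            h = hits[seq]
            if not h.species_at_best:
                n_unassigned += n
            elif h.is_multi_hit:
                key = tuple(sorted(h.species_at_best))
                multi[key] += 1
                multi_reads[key] += n
                n_multi += n
            else:
                counts[next(iter(h.species_at_best))] += n
                n_assigned += n
        rows.append(pd.Series(counts, name=sample))
        tally_rows.append({"sample": sample, "assigned": n_assigned,
                           "multi_hit": n_multi, "unassigned": n_unassigned})

    counts_df = pd.DataFrame(rows)
    counts_df.index.name = "sample"
    if metadata is None:
        metadata = pd.DataFrame(index=counts_df.index)
    mh = pd.DataFrame(
        [{"species_set": "; ".join(k), "n_cases": multi[k], "n_reads": multi_reads[k]}
         for k in sorted(multi)],
        columns=["species_set", "n_cases", "n_reads"],
    )
    tallies = pd.DataFrame(tally_rows).set_index("sample")
    matrix = CommunityMatrix(counts_df, metadata, marker_id)
    return AssignmentResult(matrix, mh, tallies, hits)


@dataclass
class OTU:
    representative_seq: str
    member_count: int
    best_reference_identity: float | None = None
    phylum: str | None = None


def cluster_otus(
    inserts: "Counter[str] | list[str]",
    similarity: float = 0.97,
    drop_singletons: bool = True,
) -> list[OTU]:
    """Greedy abundance-sorted centroid clustering at ``similarity``.

    Unique sequences are visited in order of decreasing abundance
    (ties broken lexicographically); each joins the first existing centroid
    it matches at >= similarity, otherwise it founds a new OTU.  OTUs whose
    total member read count is 1 (singletons) are removed.
    """
    counter = inserts if isinstance(inserts, Counter) else Counter(inserts)
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    centroids: list[str] = []
    totals: list[int] = []
    for seq, n in ordered:
        L = len(seq)
        k = max_edit_distance(L, similarity)
        placed = False
        for i, cen in enumerate(centroids):
            if abs(len(cen) - L) > k:
                continue
            # banded distance gives a cheap identity lower bound (L-d)/L;
            # only borderline cases need the exact column count
            d = banded_distance(seq, cen, k)
            if d < 0:
                continue
            if (L - d) / L >= similarity or pairwise_identity(seq, cen) >= similarity:
                totals[i] += n
                placed = True
                break
        if not placed:
            centroids.append(seq)
            totals.append(n)
    otus = [OTU(c, t) for c, t in zip(centroids, totals)]
    if drop_singletons:
        otus = [o for o in otus if o.member_count >= 2]
    return otus


def assignability_profile(
    otus: list[OTU],
    db: list[ReferenceRecord],
    lower: float = 0.80,
    assign_threshold: float = 0.97,
) -> pd.DataFrame:
    """Per-phylum fraction of OTUs identifiable at the species level.

    Each OTU representative is matched against the curated database; OTUs
    with best identity in [assign_threshold, 1] count as species-level,
    those in [lower, assign_threshold) as below-species; OTUs below
    ``lower`` are reported in a separate ``out_of_range`` row (their phylum
    cannot be trusted).  The ``lower`` bound is configurable (0.80 or 0.85
    are the conventional choices).
    """
    if not otus:
        raise ValueError("empty OTU set")
    refs = [(rec.species_name, rec.sequence) for rec in db]
    rows = []
    for otu in otus:
        ident, idx = best_hits(otu.representative_seq, refs, min_identity=lower)
        if idx:
            otu.best_reference_identity = ident
            otu.phylum = db[idx[0]].phylum
            rows.append({"phylum": otu.phylum, "identity": ident})
        else:
            otu.best_reference_identity = None
            rows.append({"phylum": "out_of_range", "identity": np.nan})

    df = pd.DataFrame(rows)
    out = []
    for phylum, grp in df.groupby("phylum"):
        if phylum == "out_of_range":
            out.append({"phylum": phylum, "n_otus": len(grp),
                        "n_species_level": 0, "fraction_species_level": np.nan})
            continue
        n_assign = int((grp["identity"] >= assign_threshold).sum())
        out.append({
            "phylum": phylum,
            "n_otus": len(grp),
            "n_species_level": n_assign,
            "fraction_species_level": n_assign / len(grp),
        })
    prof = pd.DataFrame(out).set_index("phylum")
    in_range = prof.drop(index="out_of_range", errors="ignore")
    prof.attrs["overall_fraction"] = (
        in_range["n_species_level"].sum() / in_range["n_otus"].sum()
        if in_range["n_otus"].sum() else np.nan
    )
    prof.attrs["lower_bound"] = lower
    return prof
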