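"""In-silico audit of reference-database completeness for species checklists.

For every (checklist, database snapshot, marker) the audit reports how
many checklist species have any barcode record at all, and how many have
a record in which both primer binding sites are present (IUPAC-aware,
within a mismatch tolerance, in consistent orientation and spacing).
Both counts are reported separately because "a species is in the
database" and "our primers would amplify its barcode" are different
claims.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import pandas as pd

from .primers import PrimerDefinition, reverse_complement, scan_primer
from .reference import ReferenceRecord

DEFAULT_MAX_MISMATCH = 2


def normalize_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def primer_site_match(
    record: ReferenceRecord | str,
    primer_def: PrimerDefinition,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    spacing_tolerance: float = 0.10,
) -> tuple[bool, tuple[int, int] | None]:
    """Does the record contain both primer sites for this marker?

    True iff the forward primer and the reverse-complemented reverse
    primer both occur (each within ``max_mismatch``), with the forward
    site upstream and an inter-site insert length within ±10% of the
    marker's expected insert length.  Returns the (forward, reverse)
    offsets of the first qualifying geometry.
    """
    seq = record.sequence if isinstance(record, ReferenceRecord) else record
    fhits = scan_primer(seq, primer_def.forward_seq, max_mismatch)
    if not fhits:
        return False, None
    rhits = scan_primer(seq, primer_def.reverse_rc, max_mismatch)
    if not rhits:
        return False, None
    lo = primer_def.expected_insert_len * (1 - spacing_tolerance)
    hi = primer_def.expected_insert_len * (1 + spacing_tolerance)
    lf = len(primer_def.forward_seq)
    for fpos, _ in fhits:
        for rpos, _ in rhits:
            insert_len = rpos - (fpos + lf)
            if lo <= insert_len <= hi:
                return True, (fpos, rpos)
    return False, None


def coverage_report(
    checklists: dict[str, pd.DataFrame],
    db_snapshots: dict[str, list[ReferenceRecord]],
    primer_defs: dict[str, PrimerDefinition],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> pd.DataFrame:
    """Coverage fractions per (checklist, database, marker).

    ``checklists`` maps name -> DataFrame with ``species`` (and optionally
    ``phylum``) columns.  Name matching against record species is exact
    after whitespace/case normalization; duplicate checklist names are
    collapsed with a warning.  Output columns include ``n_species``,
    ``n_with_record``, ``n_with_primer_sites`` and the corresponding
    fractions; a per-phylum breakdown is attached in ``.attrs['by_phylum']``.
    """
    rows, phylum_rows = [], []
    for db_name, records in db_snapshots.items():
        by_species: dict[str, list[ReferenceRecord]] = {}
        for rec in records:
            if rec.species_name:
                by_species.setdefault(normalize_name(rec.species_name), []).append(rec)
        site_cache: dict[tuple[str, str], bool] = {}

        for cl_name, df in checklists.items():
            if df.empty or "species" not in df.columns:
                raise ValueError("empty checklist")
            names = [normalize_name(n) for n in df["species"]]
            phyla = list(df["phylum"]) if "phylum" in df.columns else ["NA"] * len(names)
            seen = {}
            for n, p in zip(names, phyla):
                if n in seen:
                    warnings.warn(f"duplicate checklist name collapsed: {n}")
                else:
                    seen[n] = p
            for mid, pdef in primer_defs.items():
                n_record = n_sites = 0
                per_phylum: dict[str, list[int]] = {}
                for n, p in seen.items():
                    has_rec = n in by_species
                    has_sites = False
                    if has_rec:
                        key = (n, mid)
                        if key not in site_cache:
                            site_cache[key] = any(
                                primer_site_match(r, pdef, max_mismatch)[0]
                                for r in by_species[n]
                            )
                        has_sites = site_cache[key]
                    n_record += has_rec
                    n_sites += has_sites
                    acc = per_phylum.setdefault(p, [0, 0, 0])
                    acc[0] += 1
                    acc[1] += has_rec
                    acc[2] += has_sites
                n_species = len(seen)
                rows.append({
                    "checklist": cl_name, "database": db_name, "marker": mid,
                    "n_species": n_species, "n_with_record": n_record,
                    "n_with_primer_sites": n_sites,
                    "fraction_with_record": n_record / n_species,
                    "fraction_covered": n_sites / n_species,
                })
                for p, (tot, rec_c, site_c) in sorted(per_phylum.items()):
                    phylum_rows.append({
                        "checklist": cl_name, "database": db_name, "marker": mid,
                        "phylum": p, "n_species": tot, "n_with_record": rec_c,
                        "n_with_primer_sites": site_c,
                    })
    report = pd.DataFrame(rows)
    # plain records (not a DataFrame) so pandas can compare attrs on merge
    report.attrs["by_phylum"] = phylum_rows
    return report


def write_coverage_report(report: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        report.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report.to_dict(orient="records"), fh, indent=2)
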