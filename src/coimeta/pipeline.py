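"""End-to-end orchestration: simulate → process → assign → profile → stats.

`run_synthetic_pipeline` is the in-memory driver used by tests and the
acceptance script; `run_pipeline` wraps it for config-file / CLI use and
writes per-stage artifacts plus a manifest with read-count conservation
accounting.  Negative controls are reported, never subtracted.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import readproc, stats
from .coverage import coverage_report
from .matrix import CommunityMatrix
from .primers import DEFAULT_PRIMERS, PrimerDefinition
from .reference import (assign_reads, assignability_profile, cluster_otus,
                        curate_reference, write_reference_fasta)
from .simulate import (CommunityDesign, build_species_pool, default_design,
                       generate_checklist, generate_reference_db,
                       simulate_community_matrix, synthesize_reads)


@dataclass
class Thresholds:
    identity: float = 0.97
    min_overlap: int = 30
    min_insert_len: int = 270
    otu_similarity: float = 0.97
    primer_mismatches: int = 2
    max_mismatch_frac: float = 0.25
    contamination_percent: float = 1.0

    def __post_init__(self):
        if not 0.5 < self.identity <= 1:
            raise ValueError("identity threshold out of range")
        if self.min_overlap < 1 or self.min_insert_len < 0:
            raise ValueError("invalid length thresholds")


@dataclass
class PipelineResult:
    pool: list
    reference_db: list
    curated_db: list
    truth: object
    stage_counts: dict
    matrices: dict              # marker -> CommunityMatrix
    combined: CommunityMatrix | None
    multi_hit: dict             # marker -> DataFrame
    tallies: dict               # marker -> DataFrame
    otu_profiles: dict          # marker -> DataFrame
    coverage: pd.DataFrame | None
    control_summary: pd.DataFrame | None
    manifest: dict
    stats: dict = field(default_factory=dict)


def control_summary(
    matrix: CommunityMatrix,
    control_ids: list,
    contamination_percent: float = 1.0,
) -> pd.DataFrame:
    """Per-control assigned read totals as a percent of the mean real sample.

    Controls above ``contamination_percent`` of the mean non-control read
    total are flagged.  An empty control list returns an empty summary
    with a note attribute.
    """
    out = pd.DataFrame(columns=["total_reads", "percent_of_mean_sample", "flagged"])
    if not control_ids:
        out.attrs["note"] = "no negative controls in metadata"
        return out
    totals = matrix.counts.sum(axis=1)
    real = totals.drop(index=control_ids)
    mean_real = float(real.mean()) if len(real) else float("nan")
    rows = {}
    for cid in control_ids:
        tot = int(totals.get(cid, 0))
        pct = 100.0 * tot / mean_real if mean_real and mean_real > 0 else 0.0
        rows[cid] = {"total_reads": tot, "percent_of_mean_sample": pct,
                     "flagged": bool(pct > contamination_percent)}
    return pd.DataFrame.from_dict(rows, orient="index")


def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_synthetic_pipeline(
    design: CommunityDesign | None = None,
    pool_kwargs: dict | None = None,
    fraction_with_barcode: float = 1.0,
    thresholds: Thresholds | None = None,
    primers: dict[str, PrimerDefinition] | None = None,
    read_len: int = 250,
    seed: int = 0,
    run_otu_profile: bool = False,
    run_coverage: bool = False,
    run_stats: bool = False,
    outdir=None,
) -> PipelineResult:
    """Seeded synthetic end-to-end run with per-stage conservation accounting.

    The seed drives three independent generators (pool/reference,
    community, reads) spawned from one `SeedSequence`, so reruns with the
    same configuration are bit-identical.
    """
    primers = primers or DEFAULT_PRIMERS
    th = thresholds or Thresholds()
    ss = np.random.SeedSequence(seed)
    s_pool, s_ref, s_comm, s_reads = [int(c.generate_state(1)[0]) % (2**31)
                                      for c in ss.spawn(4)]

    pool = build_species_pool(seed=s_pool, **(pool_kwargs or {}))
    ref_db, pool = generate_reference_db(pool, fraction_with_barcode, seed=s_ref)
    if design is None:
        design = default_design(seed=s_comm)
    else:
        design.seed = design.seed if design.seed is not None else s_comm
    truth = simulate_community_matrix(design, pool)
    sim = synthesize_reads(truth, pool, primers, read_len=read_len, seed=s_reads)
    truth = sim.truth

    curated, curation_log = curate_reference(ref_db)

    stage_counts: dict[str, readproc.StageCounts] = {}
    per_marker: dict[str, dict[str, Counter]] = {m: {} for m in primers}
    for sid, sr in sim.samples.items():
        counters, sc = readproc.process_sample(
            sr.fwd_seq, sr.rev_seq, sr.qual, sr.qual, primers,
            min_overlap=th.min_overlap,
            max_mismatch_frac=th.max_mismatch_frac,
            primer_mismatches=th.primer_mismatches,
            min_insert_len=th.min_insert_len,
        )
        if not sc.check_partition():
            raise RuntimeError(f"read-fate partition broken in sample {sid}")
        stage_counts[sid] = sc
        for m in primers:
            per_marker[m][sid] = counters[m]

    matrices, multi_hit, tallies = {}, {}, {}
    for m in primers:
        res = assign_reads(per_marker[m], curated, threshold=th.identity,
                           metadata=truth.metadata, marker_id=m)
        matrices[m] = res.matrix
        multi_hit[m] = res.multi_hit_report
        tallies[m] = res.tallies
    combined = None
    for m in sorted(matrices):
        combined = matrices[m] if combined is None else combined.union(matrices[m])

    otu_profiles = {}
    if run_otu_profile:
        for m in primers:
            pooled: Counter = Counter()
            for c in per_marker[m].values():
                pooled.update(c)
            otus = cluster_otus(pooled, similarity=th.otu_similarity)
            if otus:
                otu_profiles[m] = assignability_profile(otus, curated)

    cov = None
    if run_coverage:
        checklists = {
            "native": generate_checklist(pool, "native"),
            "invader": generate_checklist(pool, "invader"),
        }
        checklists = {k: v for k, v in checklists.items() if not v.empty}
        cov = coverage_report(checklists, {"mock_db": curated}, primers)

    ctrl_ids = list(truth.metadata.index[truth.metadata["is_control"]])
    ctrl = control_summary(combined, ctrl_ids, th.contamination_percent) \
        if combined is not None else None

    stats_out = {}
    if run_stats and combined is not None:
        real = combined.subset(
            [s for s in combined.samples if s not in ctrl_ids]
        ).drop_empty_species()
        groups = real.metadata["habitat"]
        if groups.nunique() >= 2 and groups.value_counts().min() >= 2:
            dm = stats.hellinger_distance(real.counts)
            stats_out["permanova_habitat"] = stats.permanova(
                dm, groups.to_numpy(), seed=seed
            )
            stats_out["simper_habitat"] = stats.simper(real.counts, groups.to_numpy())
        stats_out["alpha"] = stats.alpha_stats(real.counts)
        stats_out["accumulation"] = stats.accumulation_curves(real.counts, seed=seed)

    conservation = pd.DataFrame({
        sid: {
            "reads_in": sc.n_input,
            "trim_discarded": sc.n_trim_discarded,
            "unmerged": sc.n_unmerged,
            "no_primer": sc.n_no_primer,
            "ambiguous": sc.n_ambiguous,
            "too_short": sc.n_too_short,
            **{f"assigned_{m}": sc.n_assigned[m] for m in primers},
        }
        for sid, sc in stage_counts.items()
    }).T
    manifest = {
        "config_hash": _config_hash({
            "fraction_with_barcode": fraction_with_barcode,
            "thresholds": asdict(th), "read_len": read_len, "seed": seed,
            "design": {"reads_per_sample": design.reads_per_sample,
                       "error_rate": design.error_rate,
                       "n_sites": len(design.sites)},
        }),
        "seed": seed,
        "n_samples": len(sim.samples),
        "n_species_pool": len(pool),
        "n_reference_records": len(ref_db),
        "n_curated_records": len(curated),
        "curation_removals": len(curation_log),
        "conservation": conservation.to_dict(orient="index"),
    }
    result = PipelineResult(
        pool=pool, reference_db=ref_db, curated_db=curated, truth=truth,
        stage_counts=stage_counts, matrices=matrices, combined=combined,
        multi_hit=multi_hit, tallies=tallies, otu_profiles=otu_profiles,
        coverage=cov, control_summary=ctrl, manifest=manifest,
    )
    result.manifest["stats"] = sorted(stats_out) if stats_out else []
    result.stats = stats_out

    if outdir is not None:
        _write_outputs(result, sim, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, sim, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_reference_fasta(result.reference_db, outdir / "reference.fasta")
    sim.write_fastq(outdir / "reads")
    result.truth.counts.to_csv(outdir / "truth_counts.tsv", sep="\t")
    result.truth.metadata.to_csv(outdir / "sample_metadata.tsv", sep="\t")
    if result.truth.per_read is not None:
        result.truth.per_read.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    for m, mat in result.matrices.items():
        mat.to_tsv(outdir / f"community_{m}.tsv")
        result.multi_hit[m].to_csv(outdir / f"multihit_{m}.tsv", sep="\t", index=False)
    if result.combined is not None:
        result.combined.to_tsv(outdir / "community_combined.tsv")
    if result.coverage is not None:
        result.coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    if result.control_summary is not None:
        result.control_summary.to_csv(outdir / "control_summary.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def run_pipeline(config: dict) -> PipelineResult:
    """Config-dict entry point (YAML/JSON via the CLI).

    Recognised keys: seed, outdir, fraction_with_barcode, read_len,
    pool (kwargs for build_species_pool), design (reads_per_sample,
    error_rate, n_controls), thresholds (Thresholds fields), stages
    (subset of {otu_profile, coverage, stats}).
    """
    seed = int(config.get("seed", 0))
    th = Thresholds(**config.get("thresholds", {}))
    design_cfg = dict(config.get("design", {}))
    design = default_design(seed=seed, **design_cfg) if design_cfg else None
    stages = set(config.get("stages", ["otu_profile", "coverage", "stats"]))
    return run_synthetic_pipeline(
        design=design,
        pool_kwargs=config.get("pool", {}),
        fraction_with_barcode=float(config.get("fraction_with_barcode", 1.0)),
        thresholds=th,
        read_len=int(config.get("read_len", 250)),
        seed=seed,
        run_otu_profile="otu_profile" in stages,
        run_coverage="coverage" in stages,
        run_stats="stats" in stages,
        outdir=config.get("outdir"),
    )
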