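"""Synthetic eDNA metabarcoding inputs with known ground truth.

Everything downstream is exercised on data from this module: a mock
BOLD-style barcode reference, native/invader species checklists, and
paired-end amplicon reads with planted spatial/seasonal community
structure plus near-empty negative controls.

Mock barcodes are laid out like the real Folmer COI region: the two
amplicons overlap, with the COI1 forward primer site nested inside the
COI2 insert.  Species within a genus diverge by rejection-sampled
mutation so that congeners sit at 80-90% identity over both insert
windows (below the species-assignment threshold, inside the profiling
band), while unrelated genera are far more divergent.  A designated
"sister pair" at ~98-99% identity exercises the multiple-hit logic.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import pairwise_identity
from .primers import DEFAULT_PRIMERS, PrimerDefinition, concrete_site, reverse_complement
from .reference import ReferenceRecord

PHYLA = [
    "Annelida", "Arthropoda", "Bryozoa", "Chordata", "Cnidaria",
    "Echinodermata", "Mollusca", "Nemertea", "Porifera", "Rotifera",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _BASE_TO_IDX[b] = i
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[a] = b


# ---------------------------------------------------------------------------
# barcode layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeLayout:
    """Coordinates of primer sites and amplicon windows within a barcode."""

    total_len: int
    sites: dict            # name -> (start, end), concrete-site regions
    amplicons: dict        # marker_id -> (start, end)
    inserts: dict          # marker_id -> (start, end)

    @property
    def frozen_mask(self) -> np.ndarray:
        mask = np.zeros(self.total_len, dtype=bool)
        for s, e in self.sites.values():
            mask[s:e] = True
        return mask


def default_layout(
    primers: dict[str, PrimerDefinition] | None = None,
    pad5: int = 100,
    spacer: int = 60,
    total_len: int = 650,
) -> BarcodeLayout:
    """Nested two-amplicon layout mirroring the real COI barcode region."""
    primers = primers or DEFAULT_PRIMERS
    p1, p2 = primers["COI1"], primers["COI2"]
    lf2, lr2 = len(p2.forward_seq), len(p2.reverse_seq)
    lf1, lr1 = len(p1.forward_seq), len(p1.reverse_seq)
    ins1, ins2 = p1.expected_insert_len, p2.expected_insert_len

    f2_s = pad5
    f2_e = f2_s + lf2                      # COI2 forward site
    f1_s = f2_e + spacer
    f1_e = f1_s + lf1                      # COI1 forward site (inside COI2 insert)
    y = ins2 - spacer - lf1                # COI2 insert tail after COI1 fwd site
    r2_s = f2_e + ins2
    r2_e = r2_s + lr2                      # COI2 reverse site (rc) ends COI2 amplicon
    z = ins1 - y - lr2
    if y <= 0 or z < 0:
        raise ValueError("primer/insert lengths incompatible with nested layout")
    r1_s = r2_e + z
    r1_e = r1_s + lr1                      # COI1 reverse site (rc)
    if r1_e + 1 > total_len:
        raise ValueError("total_len too short for layout")
    return BarcodeLayout(
        total_len=total_len,
        sites={"COI2_f": (f2_s, f2_e), "COI1_f": (f1_s, f1_e),
               "COI2_r": (r2_s, r2_e), "COI1_r": (r1_s, r1_e)},
        amplicons={"COI1": (f1_s, r1_e), "COI2": (f2_s, r2_e)},
        inserts={"COI1": (f1_e, r1_s), "COI2": (f2_e, r2_s)},
    )


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------

@dataclass
class MockSpecies:
    species_name: str
    phylum: str
    habitat_class: str                 # marine | freshwater | brackish | terrestrial
    barcode_seq: str
    genus: str
    layout: BarcodeLayout
    in_reference: bool = False
    on_native_checklist: bool = False
    on_invader_checklist: bool = False
    sister_of: str | None = None

    def amplicon(self, marker_id: str) -> str:
        s, e = self.layout.amplicons[marker_id]
        return self.barcode_seq[s:e]

    def insert(self, marker_id: str) -> str:
        s, e = self.layout.inserts[marker_id]
        return self.barcode_seq[s:e]


def _mutate_str(seq: np.ndarray, mutable: np.ndarray, rate: float,
                rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    pos = mutable[rng.random(mutable.size) < rate]
    if pos.size:
        idx = _BASE_TO_IDX[out[pos]]
        out[pos] = _BASES[(idx + rng.integers(1, 4, size=pos.size)) % 4]
    return out


def _window_identities(a: np.ndarray, b: np.ndarray, layout: BarcodeLayout) -> list[float]:
    idents = []
    for s, e in layout.inserts.values():
        ident = float(np.mean(a[s:e] == b[s:e]))
        idents.append(ident)
    return idents


def build_species_pool(
    n_species: int = 60,
    genus_size: int = 6,
    n_terrestrial: int = 2,
    n_freshwater: int = 4,
    n_brackish: int = 4,
    n_invaders: int = 10,
    sister_pair: bool = True,
    sister_divergence: float = 0.012,
    divergence: float = 0.083,
    identity_band: tuple[float, float] = (0.805, 0.895),
    enforce_identity_band: bool = True,
    primers: dict[str, PrimerDefinition] | None = None,
    seed: int = 0,
) -> list[MockSpecies]:
    """Generate the mock species pool with genus-structured barcodes.

    ``n_species`` aquatic species are organised into genera of
    ``genus_size``; ``n_terrestrial`` extra terrestrial species (their own
    genus) model contaminant reference records and never appear on aquatic
    checklists.  Within-genus insert identity is rejection-sampled into
    ``identity_band``; one designated sister pair sits near 98-99%.
    """
    if n_species < 1:
        raise ValueError("no species")
    primers = primers or DEFAULT_PRIMERS
    layout = default_layout(primers)
    rng = np.random.default_rng(seed)
    mutable = np.flatnonzero(~layout.frozen_mask)
    lo, hi = identity_band

    def make_ancestor() -> np.ndarray:
        arr = _BASES[rng.integers(0, 4, size=layout.total_len)]
        # write concrete per-genus primer-site realizations
        site_seqs = {
            "COI1_f": concrete_site(primers["COI1"].forward_seq, rng),
            "COI1_r": reverse_complement(concrete_site(primers["COI1"].reverse_seq, rng)),
            "COI2_f": concrete_site(primers["COI2"].forward_seq, rng),
            "COI2_r": reverse_complement(concrete_site(primers["COI2"].reverse_seq, rng)),
        }
        for name, (s, e) in layout.sites.items():
            arr[s:e] = np.frombuffer(site_seqs[name].encode(), dtype=np.uint8)
        return arr

    n_genera = math.ceil(n_species / genus_size)
    pool: list[MockSpecies] = []
    for g in range(n_genera):
        genus = f"Genus{g:03d}"
        phylum = PHYLA[g % len(PHYLA)]
        ancestor = make_ancestor()
        size = min(genus_size, n_species - g * genus_size)
        members: list[np.ndarray] = []
        for j in range(size):
            is_sister = sister_pair and g == 0 and j == 1 and size >= 2
            template = members[0] if is_sister else ancestor
            rate = sister_divergence if is_sister else divergence
            band = (0.97, 0.996) if is_sister else (lo, hi)
            best, best_score = None, np.inf
            for _ in range(80):
                cand = _mutate_str(template, mutable, rate, rng)
                if not enforce_identity_band or not members:
                    best = cand
                    break
                idents = []
                others = [members[0]] if is_sister else members
                for m in others:
                    idents.extend(_window_identities(cand, m, layout))
                if is_sister:
                    ok = all(band[0] <= i <= band[1] for i in idents)
                else:
                    ok = all(band[0] <= i <= band[1] for i in idents)
                if ok:
                    best = cand
                    break
                score = sum(
                    max(0.0, band[0] - i) + max(0.0, i - band[1]) for i in idents
                )
                if score < best_score:
                    best, best_score = cand, score
            members.append(best)
            sp = MockSpecies(
                species_name=f"{genus} species{j:02d}",
                phylum=phylum,
                habitat_class="marine",
                barcode_seq=best.tobytes().decode("ascii"),
                genus=genus,
                layout=layout,
                sister_of=f"{genus} species00" if is_sister else None,
            )
            pool.append(sp)
        if len(pool) >= n_species:
            break
    pool = pool[:n_species]

    # habitat classes among aquatic species (never the sister pair's genus
    # partner semantics — habitat is independent of barcode structure)
    aquatic_idx = np.arange(len(pool))
    special = rng.choice(aquatic_idx, size=min(n_freshwater + n_brackish, len(pool)),
                         replace=False)
    for k, i in enumerate(special):
        pool[i].habitat_class = "freshwater" if k < n_freshwater else "brackish"

    # invader flags among marine species; natives are the remaining aquatic taxa
    marine_idx = [i for i, s in enumerate(pool) if s.habitat_class == "marine"]
    inv = rng.choice(marine_idx, size=min(n_invaders, len(marine_idx)), replace=False)
    for i in inv:
        pool[i].on_invader_checklist = True
    for s in pool:
        s.on_native_checklist = not s.on_invader_checklist

    # terrestrial contaminant species in their own genus
    terra_phyla = ["Arthropoda", "Chordata"]
    if n_terrestrial:
        ancestor = make_ancestor()
        for j in range(n_terrestrial):
            bc = _mutate_str(ancestor, mutable, divergence, rng)
            pool.append(MockSpecies(
                species_name=f"Terragenus species{j:02d}",
                phylum=terra_phyla[j % 2],
                habitat_class="terrestrial",
                barcode_seq=bc.tobytes().decode("ascii"),
                genus="Terragenus",
                layout=layout,
            ))

    names = [s.species_name for s in pool]
    if len(set(names)) != len(names):
        raise RuntimeError("species names not unique")
    return pool


# ---------------------------------------------------------------------------
# reference database & checklists
# ---------------------------------------------------------------------------

def generate_reference_db(
    species_pool: list[MockSpecies],
    fraction_with_barcode: float,
    seed: int = 0,
    include_unnamed: bool = True,
) -> tuple[list[ReferenceRecord], list[MockSpecies]]:
    """Give exactly round(fraction × pool size) species a barcode record.

    Carriers are drawn stratified over the native / invader / other strata
    so each checklist's coverage tracks the global fraction.  At least one
    terrestrial species is forced among the carriers (when the pool has
    one) and one extra record lacking a species-level name is emitted, so
    downstream curation filters always have something to remove.
    """
    if not species_pool:
        raise ValueError("no species")
    if not 0 <= fraction_with_barcode <= 1:
        raise ValueError("fraction_with_barcode must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_total = round(fraction_with_barcode * len(species_pool))

    strata: dict[str, list[MockSpecies]] = {"native": [], "invader": [], "other": []}
    for s in species_pool:
        s.in_reference = False
        if s.on_invader_checklist:
            strata["invader"].append(s)
        elif s.on_native_checklist:
            strata["native"].append(s)
        else:
            strata["other"].append(s)

    alloc = {k: round(fraction_with_barcode * len(v)) for k, v in strata.items()}
    order = sorted(strata, key=lambda k: -len(strata[k]))
    while sum(alloc.values()) != n_total:
        delta = n_total - sum(alloc.values())
        for k in order:
            if delta > 0 and alloc[k] < len(strata[k]):
                alloc[k] += 1
                break
            if delta < 0 and alloc[k] > 0:
                alloc[k] -= 1
                break

    carriers: list[MockSpecies] = []
    for k in sorted(strata):
        members = sorted(strata[k], key=lambda s: s.species_name)
        idx = rng.choice(len(members), size=alloc[k], replace=False) if alloc[k] else []
        carriers.extend(members[i] for i in sorted(idx))

    terrestrial = [s for s in species_pool if s.habitat_class == "terrestrial"]
    if terrestrial and n_total >= 1 and not any(
        s.habitat_class == "terrestrial" for s in carriers
    ):
        swap = max(range(len(carriers)),
                   key=lambda i: carriers[i].species_name) if carriers else None
        if swap is not None:
            carriers[swap] = terrestrial[0]

    records: list[ReferenceRecord] = []
    for i, s in enumerate(sorted(carriers, key=lambda s: s.species_name)):
        s.in_reference = True
        records.append(ReferenceRecord(
            record_id=f"REC{i:05d}",
            species_name=s.species_name,
            phylum=s.phylum,
            sequence=s.barcode_seq,
            habitat=s.habitat_class,
        ))
    if include_unnamed:
        non_carriers = [s for s in species_pool if not s.in_reference]
        src = sorted(non_carriers or species_pool, key=lambda s: s.species_name)[0]
        records.append(ReferenceRecord(
            record_id="RECUNNAMED",
            species_name=None,
            phylum=src.phylum,
            sequence=src.barcode_seq,
            habitat=src.habitat_class,
        ))
    return records, species_pool


def generate_checklist(species_pool: list[MockSpecies], list_kind: str) -> pd.DataFrame:
    """Tabular species checklist (native Arctic taxa or potential invaders)."""
    if list_kind not in {"native", "invader"}:
        raise ValueError("list_kind must be 'native' or 'invader'")
    flag = "on_native_checklist" if list_kind == "native" else "on_invader_checklist"
    rows = [
        {"species": s.species_name, "phylum": s.phylum, "list_kind": list_kind}
        for s in sorted(species_pool, key=lambda s: s.species_name)
        if getattr(s, flag) and s.habitat_class != "terrestrial"
    ]
    return pd.DataFrame(rows, columns=["species", "phylum", "list_kind"])


def write_checklist(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_checklist(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# community design & truth
# ---------------------------------------------------------------------------

@dataclass
class SiteSpec:
    site_id: str
    habitat: str                        # water_column | tide_pool | shore
    depths: tuple = ("surface", "mid", "deep")
    river_influence: bool = False

    def __post_init__(self):
        if self.habitat not in {"water_column", "tide_pool", "shore"}:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.habitat != "water_column":
            self.depths = ("NA",)


@dataclass
class Effect:
    """Multiplicative abundance shift for a species subset at a factor level."""

    factor: str                         # habitat | depth | season | site
    level: str
    species: tuple
    multiplier: float

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("multipliers must be > 0")
        self.species = tuple(self.species)


@dataclass
class CommunityDesign:
    sites: list
    seasons: tuple = ("summer",)
    reads_per_sample: int = 10_000
    error_rate: float = 0.005
    base_mu: float = 0.0
    base_sigma: float = 1.0
    sample_sigma: float = 0.25          # per-sample lognormal overdispersion
    effects: list = field(default_factory=list)
    n_controls: int = 2
    control_max_stray: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")
        if not 0 <= self.error_rate < 0.03:
            raise ValueError("error_rate must be in [0, 0.03)")

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for season in self.seasons:
            for site in self.sites:
                for depth in site.depths:
                    sid = f"{site.site_id}-{depth}-{season}"
                    rows.append({
                        "sample": sid, "site": site.site_id,
                        "habitat": site.habitat, "depth": depth,
                        "season": season, "is_control": False,
                        "river_influence": site.river_influence,
                    })
        for i in range(self.n_controls):
            rows.append({
                "sample": f"CTRL{i:02d}", "site": "control", "habitat": "control",
                "depth": "NA", "season": self.seasons[0], "is_control": True,
                "river_influence": False,
            })
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class TruthTable:
    """Ground truth: per-sample species counts and, after read synthesis,
    per-read species/marker/error-count records."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    species: list
    design: CommunityDesign
    per_read: pd.DataFrame | None = None


def simulate_community_matrix(
    design: CommunityDesign, species_pool: list[MockSpecies]
) -> TruthTable:
    """Draw true per-sample species read counts from the planted design.

    Counts are multinomial(reads_per_sample, p) with p proportional to a
    species lognormal base abundance times every applicable effect
    multiplier and a per-sample lognormal jitter.  Freshwater species only
    get nonzero probability in surface samples at river-influenced sites.
    Negative controls start all-zero (strays are added at read synthesis).
    """
    rng = np.random.default_rng(design.seed)
    aquatic = sorted(
        (s for s in species_pool if s.habitat_class != "terrestrial"),
        key=lambda s: s.species_name,
    )
    names = [s.species_name for s in aquatic]
    habitat_class = np.array([s.habitat_class for s in aquatic])
    base = rng.lognormal(design.base_mu, design.base_sigma, len(aquatic))

    meta = design.sample_table()
    counts = np.zeros((len(meta), len(aquatic)), dtype=np.int64)
    for effect in design.effects:
        unknown = set(effect.species) - set(names)
        if unknown:
            raise ValueError(f"effect references unknown species: {sorted(unknown)[:3]}")
    for r, (sid, row) in enumerate(meta.iterrows()):
        if row["is_control"]:
            continue
        w = base.copy()
        for effect in design.effects:
            if str(row.get(effect.factor)) == effect.level:
                sel = np.isin(names, effect.species)
                w[sel] *= effect.multiplier
        fresh = habitat_class == "freshwater"
        if not (row["depth"] == "surface" and row["river_influence"]):
            w[fresh] = 0.0
        if design.sample_sigma > 0:
            w *= rng.lognormal(0.0, design.sample_sigma, w.size)
        if design.reads_per_sample > 0:
            counts[r] = rng.multinomial(design.reads_per_sample, w / w.sum())
    counts_df = pd.DataFrame(counts, index=meta.index, columns=names)
    return TruthTable(counts_df, meta, names, design)


# ---------------------------------------------------------------------------
# read synthesis
# ---------------------------------------------------------------------------

def make_quality_profile(read_len: int, base_q: int = 38, tail_len: int = 30,
                         tail_q: int = 25) -> np.ndarray:
    """Fixed high-quality profile with a mildly degraded 3' tail."""
    q = np.full(read_len, base_q, dtype=np.uint8)
    if tail_len > 0:
        tail = np.linspace(base_q, tail_q, min(tail_len, read_len))
        q[-len(tail):] = np.round(tail).astype(np.uint8)
    return q


@dataclass
class SampleReads:
    ids: list
    fwd_seq: np.ndarray                 # (n, read_len) ASCII uint8
    rev_seq: np.ndarray
    qual: np.ndarray                    # (read_len,) shared profile

    @property
    def n_reads(self) -> int:
        return self.fwd_seq.shape[0]


@dataclass
class ReadSimulation:
    samples: dict
    truth: TruthTable
    read_len: int
    primers: dict

    def write_fastq(self, outdir) -> dict:
        """Write gzipped paired FASTQ (Phred+33) per sample; returns paths.

        The gzip header mtime is fixed at 0 so identical runs are
        byte-identical.
        """
        import io
        from contextlib import ExitStack
        from pathlib import Path

        def gz_text(path, stack):
            raw = stack.enter_context(open(path, "wb"))
            gz = stack.enter_context(
                gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            )
            return stack.enter_context(io.TextIOWrapper(gz))

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sid, sr in self.samples.items():
            qual_str = "".join(chr(q + 33) for q in sr.qual)
            p1, p2 = outdir / f"{sid}_R1.fastq.gz", outdir / f"{sid}_R2.fastq.gz"
            with ExitStack() as stack:
                f1 = gz_text(p1, stack)
                f2 = gz_text(p2, stack)
                for i in range(sr.n_reads):
                    fs = sr.fwd_seq[i].tobytes().decode("ascii")
                    rs = sr.rev_seq[i].tobytes().decode("ascii")
                    f1.write(f"@{sr.ids[i]}/1\n{fs}\n+\n{qual_str}\n")
                    f2.write(f"@{sr.ids[i]}/2\n{rs}\n+\n{qual_str}\n")
            paths[sid] = (p1, p2)
        return paths


def synthesize_reads(
    truth: TruthTable,
    species_pool: list[MockSpecies],
    primers: dict[str, PrimerDefinition] | None = None,
    read_len: int = 250,
    seed: int = 0,
    error_rate: float | None = None,
    min_overlap: int = 30,
) -> ReadSimulation:
    """Emit paired reads for every true count, plus control stray reads.

    Each read is the species' primer-flanked amplicon with iid
    substitution errors applied once to the template, so both mates agree
    in their overlap and the per-insert substitution count is
    Binomial(insert_len, error_rate).  Marker (COI1/COI2) is a fair coin
    per read.  Negative controls receive 0..control_max_stray reads of
    random aquatic species.  Returns reads plus the completed TruthTable
    (control strays added to the counts; per-read records attached).
    """
    primers = primers or DEFAULT_PRIMERS
    if error_rate is None:
        error_rate = truth.design.error_rate
    rng = np.random.default_rng(seed)

    by_name = {s.species_name: s for s in species_pool}
    species = truth.species
    markers = sorted(primers)
    amp_arrays = {}
    for m in markers:
        amp_len = len(by_name[species[0]].amplicon(m))
        if read_len > amp_len:
            raise ValueError(f"read_len {read_len} exceeds {m} amplicon ({amp_len} nt)")
        if 2 * read_len - amp_len < min_overlap:
            raise ValueError(
                f"read_len {read_len} gives <{min_overlap} nt overlap on {m}"
            )
        amp_arrays[m] = np.vstack([
            np.frombuffer(by_name[sp].amplicon(m).encode(), dtype=np.uint8)
            for sp in species
        ])

    counts = truth.counts.copy()
    meta = truth.metadata
    is_ctrl = meta["is_control"].to_numpy()
    C = counts.to_numpy().copy()
    for r in np.flatnonzero(is_ctrl):
        n_stray = int(rng.integers(0, truth.design.control_max_stray + 1))
        stray = rng.integers(0, len(species), size=n_stray)
        for sidx in stray:
            C[r, sidx] += 1
    counts = pd.DataFrame(C, index=counts.index, columns=counts.columns)

    row_tot = C.sum(axis=1)
    sample_idx = np.repeat(np.arange(C.shape[0]), row_tot)
    species_idx = (
        np.concatenate([np.repeat(np.arange(C.shape[1]), C[r])
                        for r in range(C.shape[0])])
        if row_tot.sum() else np.zeros(0, dtype=np.int64)
    )
    n_reads = sample_idx.size
    marker_idx = rng.integers(0, len(markers), size=n_reads)

    fwd = np.zeros((n_reads, read_len), dtype=np.uint8)
    rev = np.zeros((n_reads, read_len), dtype=np.uint8)
    n_err = np.zeros(n_reads, dtype=np.int64)
    for mi, m in enumerate(markers):
        sel = np.flatnonzero(marker_idx == mi)
        if not sel.size:
            continue
        amp = amp_arrays[m][species_idx[sel]].copy()
        if error_rate > 0:
            mask = rng.random(amp.shape) < error_rate
            pos = np.nonzero(mask)
            if pos[0].size:
                idx = _BASE_TO_IDX[amp[pos]]
                amp[pos] = _BASES[(idx + rng.integers(1, 4, size=pos[0].size)) % 4]
            n_err[sel] = mask.sum(axis=1)
        fwd[sel] = amp[:, :read_len]
        rc = _COMP_LUT[amp[:, ::-1]]
        rev[sel] = rc[:, :read_len]

    qual = make_quality_profile(read_len)
    starts = np.concatenate([[0], np.cumsum(row_tot)])
    sample_names = counts.index.to_numpy()
    within = np.arange(n_reads) - starts[sample_idx]
    all_ids = [f"{sample_names[s]}:read{k:06d}"
               for s, k in zip(sample_idx, within)]
    samples: dict[str, SampleReads] = {}
    for r, sid in enumerate(counts.index):
        lo, hi = starts[r], starts[r + 1]
        samples[sid] = SampleReads(all_ids[lo:hi], fwd[lo:hi], rev[lo:hi], qual)
    per_read = pd.DataFrame({
        "sample": sample_names[sample_idx],
        "read_id": all_ids,
        "species": np.asarray(species, dtype=object)[species_idx],
        "marker": np.asarray(markers, dtype=object)[marker_idx],
        "n_errors": n_err,
    }, columns=["sample", "read_id", "species", "marker", "n_errors"])
    completed = TruthTable(counts, meta, species, truth.design, per_read)
    return ReadSimulation(samples, completed, read_len, primers)


# ---------------------------------------------------------------------------
# canned designs
# ---------------------------------------------------------------------------

def default_design(seed: int = 0, reads_per_sample: int = 10_000,
                   error_rate: float = 0.005,
                   affected_species: tuple = (), **kwargs) -> CommunityDesign:
    """Survey-like layout: 4 water-column sites × 3 depths + 4 tide pools
    + 2 field controls, one summer season, a ×3 tide-pool effect."""
    sites = [SiteSpec(f"WC{i}", "water_column",
                      river_influence=(i == 0)) for i in range(4)]
    sites += [SiteSpec(f"TP{i}", "tide_pool") for i in range(4)]
    effects = []
    if affected_species:
        effects.append(Effect("habitat", "tide_pool", tuple(affected_species), 3.0))
    return CommunityDesign(sites=sites, reads_per_sample=reads_per_sample,
                           error_rate=error_rate, effects=effects, seed=seed,
                           **kwargs)


def habitat_effect_design(
    species_pool: list[MockSpecies],
    n_per_group: int = 8,
    reads_per_sample: int = 10_000,
    multiplier: float = 3.0,
    n_affected: int = 10,
    error_rate: float = 0.0,
    seed: int = 0,
) -> CommunityDesign:
    """The planted habitat contrast: n water-column vs n tide-pool samples
    with a ×multiplier boost on ``n_affected`` marine species in pools."""
    marine = sorted(s.species_name for s in species_pool
                    if s.habitat_class == "marine")
    sites = [SiteSpec(f"WC{i}", "water_column", depths=("surface",))
             for i in range(n_per_group)]
    sites += [SiteSpec(f"TP{i}", "tide_pool") for i in range(n_per_group)]
    return CommunityDesign(
        sites=sites,
        reads_per_sample=reads_per_sample,
        error_rate=error_rate,
        effects=[Effect("habitat", "tide_pool", tuple(marine[:n_affected]), multiplier)],
        n_controls=0,
        seed=seed,
    )


def null_design(n_samples: int = 12, reads_per_sample: int = 1_000,
                error_rate: float = 0.0, seed: int = 0) -> CommunityDesign:
    """Exchangeable null: identical water-column surface sites, no effects."""
    sites = [SiteSpec(f"S{i:02d}", "water_column", depths=("surface",))
             for i in range(n_samples)]
    return CommunityDesign(sites=sites, reads_per_sample=reads_per_sample,
                           error_rate=error_rate, n_controls=0, seed=seed)
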