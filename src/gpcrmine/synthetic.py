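"""Synthetic proteomes with planted, fully known architectures.

No public accessions accompany the family inventory this package mirrors,
so every pipeline stage is exercised on generated proteomes in which the
ground truth is planted and recorded: 7TM receptors with C- (or, for the
protease class, N-) terminal catalytic domains, LRxGI linkers, polytopic
decoy membrane proteins (transporters, channels), soluble kinases of the
classical types, neutral background proteins, and -- on request -- gene
models split into two fragment records to emulate a fragmented genome
assembly.

Membrane helices are drawn from the strongly hydrophobic residues
{I,L,V,F,A,M} with Kyte-Doolittle-weighted frequencies and loops from
hydrophilic residues, so a hydropathy scanner *can* find the helices
without the generator hard-coding the detection. Accessory domains are
noisy per-column emissions from the same packaged seed profiles the
scanner builds its matrices from, which makes profile scanning a real
test rather than string matching. All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify as cls
from .motif import ANCHOR_HEAD, ANCHOR_TAIL, MOTIF_LENGTH, load_spacer_frequencies
from .profiles import AA, ProfileModel, load_default_profiles
from .records import ProteinRecord
from .topology import KYTE_DOOLITTLE
from .phylo import TreeNode, parse_newick
from .wag import WAGModel, default_model

# decoy / background category labels used in the truth ledger
DECOY_TRANSPORTER = "DECOY_TRANSPORTER"
DECOY_CHANNEL = "DECOY_CHANNEL"
SOLUBLE_PIPK_I = "SOLUBLE_PIPK_I"
SOLUBLE_PIPK_II = "SOLUBLE_PIPK_II"
SOLUBLE_PIPK_III = "SOLUBLE_PIPK_III"
BACKGROUND = "BACKGROUND"

DECOY_CATEGORIES = (
    DECOY_TRANSPORTER, DECOY_CHANNEL,
    SOLUBLE_PIPK_I, SOLUBLE_PIPK_II, SOLUBLE_PIPK_III, BACKGROUND,
)

_HELIX_RESIDUES = "ILVFAM"
_HELIX_WEIGHTS = np.array([KYTE_DOOLITTLE[a] for a in _HELIX_RESIDUES])
_HELIX_WEIGHTS = _HELIX_WEIGHTS / _HELIX_WEIGHTS.sum()

# cytoplasmic loops carry the positive-inside K/R charge; the outside face
# uses D/E instead, so the orientation rule has signal to work with
_CYTO_LOOP = {"K": 0.05, "R": 0.05, "S": 0.35, "G": 0.35,
              "N": 0.05, "Q": 0.05, "P": 0.10}
_EXT_LOOP = {"D": 0.05, "E": 0.05, "S": 0.35, "G": 0.35,
             "N": 0.05, "Q": 0.05, "P": 0.10}

_LOOP_BAND = 0.45  # enforced loop mean lies within this band below the cap

# Local-composition floors that make planted helices separable from their
# flanking loops at window scale, not just on average: every 13-residue
# stretch of a helix stays strongly hydrophobic and no 6-residue stretch of
# a loop is strongly hydrophilic enough to drown a helix-edge window.
_HELIX_CORE_WINDOW = 13
_HELIX_CORE_FLOOR = 3.3
_LOOP_WINDOW = 6
_LOOP_WINDOW_FLOOR = -2.0


@dataclass
class PlantSpec:
    """One planted architecture family.

    ``helix_hydropathy_mean`` is the enforced *minimum* sample-mean
    hydropathy of each planted helix; ``loop_hydropathy_mean`` the enforced
    *maximum* for loops, so planted helices and loops are separable by
    construction without fixing the detector's hand.
    """

    class_label: str
    n_copies: int
    tm_count: int | None = None
    helix_length: int = 21
    helix_hydropathy_mean: float = 3.45
    loop_hydropathy_mean: float = -1.0
    plant_motif: bool | None = None
    with_dep: bool = False
    truncate: bool = False

    def __post_init__(self):
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")
        if self.helix_hydropathy_mean <= self.loop_hydropathy_mean:
            raise ValueError("helix hydropathy must exceed loop hydropathy")
        if self.tm_count is None:
            self.tm_count = {
                DECOY_TRANSPORTER: 11,
                DECOY_CHANNEL: 3,
                SOLUBLE_PIPK_I: 0, SOLUBLE_PIPK_II: 0, SOLUBLE_PIPK_III: 0,
                BACKGROUND: 0,
            }.get(self.class_label, 7)
        if self.tm_count < 0:
            raise ValueError("tm_count must be >= 0")
        if self.plant_motif is None:
            self.plant_motif = self.class_label == cls.GPCR_PIPK
        if self.with_dep and self.class_label != cls.GPCR_TKL:
            raise ValueError("with_dep applies to GPCR_TKL only")


@dataclass
class TruthEntry:
    protein_id: str
    class_label: str
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    domains: list[tuple[str, int, int]] = field(default_factory=list)
    motif_start: int | None = None
    fragment_partner: str | None = None
    has_dep: bool = False


@dataclass
class GroundTruth:
    """The planted-truth ledger: exactly one entry per generated record."""

    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def add(self, entry: TruthEntry) -> None:
        if entry.protein_id in self.entries:
            raise ValueError(f"duplicate truth entry {entry.protein_id}")
        self.entries[entry.protein_id] = entry

    def __getitem__(self, protein_id: str) -> TruthEntry:
        return self.entries[protein_id]

    def __len__(self) -> int:
        return len(self.entries)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries.values():
            counts[e.class_label] = counts.get(e.class_label, 0) + 1
        return counts

    def n_bigrams(self) -> int:
        return sum(1 for e in self.entries.values()
                   if e.class_label in cls.BIGRAM_CLASSES)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tclass\ttm_coords\tdomain_coords\t"
                     "motif_start\tfragment_partner\thas_dep\n")
            for e in self.entries.values():
                tm = ",".join(f"{s}-{t}" for s, t in e.tm_segments)
                dom = ";".join(f"{n}:{s}-{t}" for n, s, t in e.domains)
                fh.write(
                    f"{e.protein_id}\t{e.class_label}\t{tm}\t{dom}\t"
                    f"{e.motif_start if e.motif_start else ''}\t"
                    f"{e.fragment_partner or ''}\t{int(e.has_dep)}\n"
                )

    @classmethod
    def from_tsv(cls_, path) -> "GroundTruth":
        truth = cls_()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                pid, label, tm, dom, motif, partner, dep = (
                    line.rstrip("\n").split("\t"))
                entry = TruthEntry(protein_id=pid, class_label=label)
                if tm:
                    entry.tm_segments = [
                        tuple(int(x) for x in part.split("-"))
                        for part in tm.split(",")
                    ]
                if dom:
                    for part in dom.split(";"):
                        name, span = part.split(":")
                        s, t = span.split("-")
                        entry.domains.append((name, int(s), int(t)))
                entry.motif_start = int(motif) if motif else None
                entry.fragment_partner = partner or None
                entry.has_dep = dep == "1"
                truth.add(entry)
        return truth


# ---------------------------------------------------------------------------
# residue samplers


def _sample(rng: np.random.Generator, residues: str, weights, n: int) -> str:
    idx = rng.choice(len(residues), size=n, p=np.asarray(weights))
    return "".join(residues[i] for i in idx)


def _mean_kd(seq: str) -> float:
    return float(np.mean([KYTE_DOOLITTLE.get(a, 0.0) for a in seq]))


def _window_means(seq: str, window: int) -> np.ndarray:
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    if values.size <= window:
        return np.array([values.mean()])
    return np.convolve(values, np.ones(window) / window, mode="valid")


def _emit_helix(rng, length: int, min_mean: float, max_tries: int = 400) -> str:
    best, best_mean = None, -np.inf
    for _ in range(max_tries):
        seq = _sample(rng, _HELIX_RESIDUES, _HELIX_WEIGHTS, length)
        mean = _mean_kd(seq)
        if mean >= min_mean and (
            _window_means(seq, _HELIX_CORE_WINDOW).min() >= _HELIX_CORE_FLOOR
        ):
            return seq
        if mean > best_mean:
            best, best_mean = seq, mean
    return best


def _emit_loop(rng, length: int, composition: dict, max_mean: float,
               max_tries: int = 400) -> str:
    residues = "".join(composition)
    weights = np.array(list(composition.values()))
    weights = weights / weights.sum()
    best, best_mean = None, np.inf
    for _ in range(max_tries):
        seq = _sample(rng, residues, weights, length)
        mean = _mean_kd(seq)
        if (max_mean - _LOOP_BAND <= mean <= max_mean
                and _window_means(seq, _LOOP_WINDOW).min() >= _LOOP_WINDOW_FLOOR):
            return seq
        if mean < best_mean:
            best, best_mean = seq, mean
    return best


def _emit_background(rng, length: int) -> str:
    return _sample(rng, AA, np.full(20, 1 / 20), length)


#: Per-type kinase signature columns. Each PIPK type carries a fixed set of
#: eight type-defining residues at non-anchor columns, so the planted kinase
#: domains are type-structured the way the four real types are divergent:
#: within-type emissions share the signature, between types they differ.
#: Deterministic design constants (independent of the run seed).
def _pipk_type_signatures() -> dict[str, list[tuple[int, str]]]:
    sig_rng = np.random.default_rng(971)
    anchor_cols = set(range(8, 13)) | set(range(28, 33)) | {46, 47}
    free = [j for j in range(60) if j not in anchor_cols]
    out: dict[str, list[tuple[int, str]]] = {}
    for t in ("I", "II", "III", "IV"):
        cols = sorted(sig_rng.choice(free, size=8, replace=False))
        out[t] = [(int(j), AA[int(sig_rng.integers(0, 20))]) for j in cols]
    return out


_PIPK_TYPE_SIGNATURES = _pipk_type_signatures()


def _emit_domain(rng, profile: ProfileModel,
                 activation_variant: str | None = None,
                 pipk_type: str | None = None) -> str:
    """Noisy per-column emission from a profile's column frequencies.

    The invariant catalytic anchors of the kinase profile (DLGKS, MDYSL and
    the activation-loop dilysine) are planted literally; the activation
    dipeptide can be swapped to a type variant, and the type's signature
    residues are written over their fixed columns.
    """
    out = []
    for j in range(profile.length):
        out.append(AA[rng.choice(20, p=profile.frequencies[j])])
    seq = list("".join(out))
    if profile.name == "PIPK":
        consensus = profile.consensus
        for anchor in profile.anchors:
            pos = consensus.find(anchor)
            if pos >= 0:
                seq[pos : pos + len(anchor)] = anchor
        if pipk_type:
            for j, aa in _PIPK_TYPE_SIGNATURES[pipk_type]:
                seq[j] = aa
        if activation_variant and profile.activation_offset is not None:
            off = profile.activation_offset
            seq[off : off + len(activation_variant)] = activation_variant
    return "".join(seq)


def _emit_motif(rng, spacer_freqs: np.ndarray) -> str:
    spacer = "".join(
        AA[rng.choice(20, p=spacer_freqs[j])] for j in range(spacer_freqs.shape[0])
    )
    return ANCHOR_HEAD + spacer + ANCHOR_TAIL


# ---------------------------------------------------------------------------
# protein builders


class _Builder:
    """Accumulates sequence parts while recording planted coordinates."""

    def __init__(self):
        self.parts: list[str] = []
        self.pos = 0  # residues emitted so far

    def add(self, seq: str) -> tuple[int, int]:
        start = self.pos + 1
        self.parts.append(seq)
        self.pos += len(seq)
        return start, self.pos

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


_CLASS_TO_DOMAIN = {
    cls.GPCR_PIPK: "PIPK",
    cls.GPCR_TKL: "TKL",
    cls.GPCR_INPP: "INPP",
    cls.GPCR_AC: "AC",
    cls.GPCR_PDE: "PDE",
    cls.AP_GPCR: "AP",
    DECOY_TRANSPORTER: "TRANSPORTER",
    DECOY_CHANNEL: "CHANNEL",
}


def _build_tm_block(b: _Builder, rng, spec: PlantSpec, entry: TruthEntry,
                    first_loop_cyto: bool) -> None:
    """Alternating helices and loops; records planted TM coordinates."""
    cyto = first_loop_cyto
    for i in range(spec.tm_count):
        helix = _emit_helix(rng, spec.helix_length, spec.helix_hydropathy_mean)
        entry.tm_segments.append(b.add(helix))
        if i < spec.tm_count - 1:
            comp = _CYTO_LOOP if cyto else _EXT_LOOP
            b.add(_emit_loop(rng, int(rng.integers(16, 27)), comp,
                             spec.loop_hydropathy_mean))
            cyto = not cyto


def _build_protein(
    rng: np.random.Generator,
    spec: PlantSpec,
    protein_id: str,
    profiles: dict[str, ProfileModel],
    spacer_freqs: np.ndarray,
) -> tuple[ProteinRecord, TruthEntry]:
    entry = TruthEntry(protein_id=protein_id, class_label=spec.class_label,
                       has_dep=spec.with_dep)
    b = _Builder()
    label = spec.class_label

    if label in (cls.GPCR_PIPK, cls.GPCR_TKL, cls.GPCR_INPP,
                 cls.GPCR_AC, cls.GPCR_PDE):
        # extracellular N tail, 7TM block, cytoplasmic C-terminal enzyme
        b.add(_emit_loop(rng, int(rng.integers(14, 23)), _EXT_LOOP,
                         spec.loop_hydropathy_mean))
        _build_tm_block(b, rng, spec, entry, first_loop_cyto=True)
        b.add(_emit_loop(rng, 8, _CYTO_LOOP, spec.loop_hydropathy_mean))
        if spec.plant_motif:
            motif = _emit_motif(rng, spacer_freqs)
            entry.motif_start = b.add(motif)[0]
        b.add(_emit_loop(rng, 6, _CYTO_LOOP, spec.loop_hydropathy_mean))
        domain = _CLASS_TO_DOMAIN[label]
        variant = "KK" if domain == "PIPK" else None
        ptype = "IV" if domain == "PIPK" else None
        span = b.add(_emit_domain(rng, profiles[domain], variant, ptype))
        entry.domains.append((domain, *span))
        if spec.with_dep:
            b.add(_emit_loop(rng, 5, _CYTO_LOOP, spec.loop_hydropathy_mean))
            span = b.add(_emit_domain(rng, profiles["DEP"]))
            entry.domains.append(("DEP", *span))
        b.add(_emit_loop(rng, 8, _CYTO_LOOP, spec.loop_hydropathy_mean))

    elif label == cls.AP_GPCR:
        # signal peptide, secreted protease, then a C-terminal 7TM block
        b.add(_emit_loop(rng, 3, _EXT_LOOP, spec.loop_hydropathy_mean))
        span = b.add(_sample(rng, _HELIX_RESIDUES, _HELIX_WEIGHTS, 12))
        entry.domains.append(("SIGNAL", *span))
        b.add(_emit_loop(rng, 4, _EXT_LOOP, spec.loop_hydropathy_mean))
        span = b.add(_emit_domain(rng, profiles["AP"]))
        entry.domains.append(("AP", *span))
        b.add(_emit_loop(rng, 12, _EXT_LOOP, spec.loop_hydropathy_mean))
        _build_tm_block(b, rng, spec, entry, first_loop_cyto=True)
        b.add(_emit_loop(rng, 15, _CYTO_LOOP, spec.loop_hydropathy_mean))

    elif label in (DECOY_TRANSPORTER, DECOY_CHANNEL):
        b.add(_emit_loop(rng, int(rng.integers(10, 20)), _EXT_LOOP,
                         spec.loop_hydropathy_mean))
        _build_tm_block(b, rng, spec, entry, first_loop_cyto=True)
        b.add(_emit_loop(rng, 6, _CYTO_LOOP, spec.loop_hydropathy_mean))
        domain = _CLASS_TO_DOMAIN[label]
        span = b.add(_emit_domain(rng, profiles[domain]))
        entry.domains.append((domain, *span))
        b.add(_emit_loop(rng, 8, _CYTO_LOOP, spec.loop_hydropathy_mean))

    elif label in (SOLUBLE_PIPK_I, SOLUBLE_PIPK_II, SOLUBLE_PIPK_III):
        b.add(_emit_background(rng, int(rng.integers(25, 45))))
        if label == SOLUBLE_PIPK_III:
            span = b.add(_emit_domain(rng, profiles["FYVE"]))
            entry.domains.append(("FYVE", *span))
            b.add(_emit_background(rng, 10))
        variant = "RK" if label == SOLUBLE_PIPK_II else "KK"
        ptype = label.rsplit("_", 1)[1]
        span = b.add(_emit_domain(rng, profiles["PIPK"], variant, ptype))
        entry.domains.append(("PIPK", *span))
        b.add(_emit_background(rng, int(rng.integers(20, 40))))

    elif label == BACKGROUND:
        b.add(_emit_background(rng, int(rng.integers(120, 401))))

    else:
        raise ValueError(f"unknown class label {label!r}")

    return ProteinRecord(id=protein_id, seq=b.sequence), entry


# ---------------------------------------------------------------------------
# public generator API


def generate_proteome(
    specs: list[PlantSpec],
    n_background: int = 0,
    seed: int = 0,
    species: str = "Simsp",
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate a proteome with planted architectures and its truth ledger.

    Deterministic for a given seed: the same call produces byte-identical
    sequences and truth.
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    if not specs and n_background == 0:
        raise ValueError("nothing to generate")
    rng = np.random.default_rng(seed)
    profiles = load_default_profiles()
    spacer = load_spacer_frequencies()
    records: list[ProteinRecord] = []
    truth = GroundTruth()
    counter: dict[str, int] = {}
    for spec in specs:
        for _ in range(spec.n_copies):
            k = counter.get(spec.class_label, 0) + 1
            counter[spec.class_label] = k
            suffix = "_DEP" if spec.with_dep else ""
            pid = f"{species}|{spec.class_label}{suffix}_{k:03d}"
            record, entry = _build_protein(rng, spec, pid, profiles, spacer)
            records.append(record)
            truth.add(entry)
    for i in range(n_background):
        pid = f"{species}|{BACKGROUND}_{i + 1:03d}"
        record, entry = _build_protein(
            rng, PlantSpec(BACKGROUND, 1), pid, profiles, spacer)
        records.append(record)
        truth.add(entry)
    return records, truth


def pinf_like_specs() -> tuple[list[PlantSpec], int]:
    """The packaged preset mirroring the reference receptor-enzyme census.

    44 bigrams -- 12 receptor-kinase (PIPK), 17 receptor-TKL of which 8
    DEP-bearing, 7 receptor-phosphatase (INPP), 4 receptor-cyclase (AC),
    3 receptor-phosphodiesterase (PDE) and a single protease-receptor
    (AP-GPCR) -- mixed with 200 decoys: 50 transporters, 50 channels, 40
    soluble kinases of the classical types and 60 background proteins.
    Returns (specs, n_background).
    """
    specs = [
        PlantSpec(cls.GPCR_PIPK, 12),
        PlantSpec(cls.GPCR_TKL, 9),
        PlantSpec(cls.GPCR_TKL, 8, with_dep=True),
        PlantSpec(cls.GPCR_INPP, 7),
        PlantSpec(cls.GPCR_AC, 4),
        PlantSpec(cls.GPCR_PDE, 3),
        PlantSpec(cls.AP_GPCR, 1),
        PlantSpec(DECOY_TRANSPORTER, 50),
        PlantSpec(DECOY_CHANNEL, 50),
        PlantSpec(SOLUBLE_PIPK_I, 12),
        PlantSpec(SOLUBLE_PIPK_II, 12),
        PlantSpec(SOLUBLE_PIPK_III, 16),
    ]
    return specs, 60


def fragment_model(
    record: ProteinRecord,
    breakpoint: int,
    truth: GroundTruth,
    overlap: int = 5,
) -> tuple[ProteinRecord, ProteinRecord]:
    """Split a planted receptor-kinase into two fragment gene models.

    ``breakpoint`` is the 1-based first residue of the second fragment; the
    first fragment additionally duplicates ``overlap`` residues past the
    breakpoint (a configurable 0-10 residue assembly overlap). Removing the
    duplicated overlap and concatenating reconstructs the original. Truth
    entries for both fragments are added with symmetric partner links.
    """
    entry = truth[record.id]
    if entry.class_label != cls.GPCR_PIPK:
        raise ValueError("fragmentation is defined for planted GPCR_PIPKs")
    if not (0 <= overlap <= 10):
        raise ValueError("overlap must be within 0-10 residues")
    n = len(record.seq)
    if not (2 <= breakpoint <= n):
        raise ValueError(f"breakpoint {breakpoint} outside (1, {n}]")
    a_seq = record.seq[: breakpoint - 1 + overlap]
    b_seq = record.seq[breakpoint - 1 :]
    id_a = f"{record.id}_fragA"
    id_b = f"{record.id}_fragB"
    frag_a = ProteinRecord(id=id_a, seq=a_seq)
    frag_b = ProteinRecord(id=id_b, seq=b_seq)

    def clip(spans, lo, hi, shift):
        out = []
        for name, s, e in spans:
            s2, e2 = max(s, lo), min(e, hi)
            if s2 <= e2:
                out.append((name, s2 - shift, e2 - shift))
        return out

    end_a = breakpoint - 1 + overlap
    entry_a = TruthEntry(
        protein_id=id_a, class_label="FRAGMENT",
        tm_segments=[(s, min(e, end_a)) for s, e in entry.tm_segments
                     if s <= end_a],
        domains=clip(entry.domains, 1, end_a, 0),
        motif_start=(entry.motif_start
                     if entry.motif_start
                     and entry.motif_start + MOTIF_LENGTH - 1 <= end_a
                     else None),
        fragment_partner=id_b,
    )
    entry_b = TruthEntry(
        protein_id=id_b, class_label="FRAGMENT",
        tm_segments=[(max(s, breakpoint) - breakpoint + 1, e - breakpoint + 1)
                     for s, e in entry.tm_segments if e >= breakpoint],
        domains=clip(entry.domains, breakpoint, n, breakpoint - 1),
        motif_start=(entry.motif_start - breakpoint + 1
                     if entry.motif_start and entry.motif_start >= breakpoint
                     else None),
        fragment_partner=id_a,
    )
    truth.add(entry_a)
    truth.add(entry_b)
    return frag_a, frag_b


def divergent_pipk_family(
    n_copies: int = 20,
    seed: int = 0,
    helix_noise: float = 0.4,
    domain_noise: float = 0.7,
) -> tuple[list[str], dict[str, tuple[int, int]]]:
    """A cross-species-style receptor-kinase family for conservation studies.

    The clean preset emits every copy from one species-like generator, so
    its kinase domains are nearly as conserved as the linker. Real
    conservation profiles come from families that diverged across taxa:
    helices keep only their hydrophobic character, the kinase domain keeps
    its catalytic anchors but little else, and the 13-residue linker motif
    stays sharp. This builder emulates that regime with a fixed architecture
    (every copy has identical region lengths, so the rows are an alignment
    as emitted): ``helix_noise`` of helix positions come from small/polar
    residues, the kinase emission is mixed ``domain_noise``-deep with a
    uniform background (anchors stay literal), and loops are uniform over
    hydrophilic residues.

    Returns the aligned rows plus the 1-based column spans of the planted
    regions ("tm", "linker", "motif", "pipk").
    """
    rng = np.random.default_rng(seed)
    profiles = load_default_profiles()
    spacer = load_spacer_frequencies()
    pipk = profiles["PIPK"]
    helix_alt = "STG"
    loop_alphabet = "DEGHKNPQRSTY"

    def noisy_helix(length=21):
        return "".join(
            (rng.choice(list(helix_alt)) if rng.random() < helix_noise
             else _sample(rng, _HELIX_RESIDUES, _HELIX_WEIGHTS, 1))
            for _ in range(length)
        )

    def noisy_domain():
        out = []
        for j in range(pipk.length):
            if rng.random() < domain_noise:
                out.append(AA[rng.integers(0, 20)])
            else:
                out.append(AA[rng.choice(20, p=pipk.frequencies[j])])
        seq = list("".join(out))
        consensus = pipk.consensus
        for anchor in pipk.anchors:
            pos = consensus.find(anchor)
            if pos >= 0:
                seq[pos : pos + len(anchor)] = anchor
        return "".join(seq)

    def loop(length):
        return "".join(rng.choice(list(loop_alphabet)) for _ in range(length))

    rows = []
    spans: dict[str, tuple[int, int]] = {}
    for _ in range(n_copies):
        b = _Builder()
        b.add(loop(18))
        tm_start = b.pos + 1
        for i in range(7):
            b.add(noisy_helix())
            if i < 6:
                b.add(loop(20))
        tm_end = b.pos
        linker_start = b.pos + 1
        b.add(loop(8))
        motif_span = b.add(_emit_motif(rng, spacer))
        b.add(loop(6))
        linker_end = b.pos
        pipk_span = b.add(noisy_domain())
        b.add(loop(10))
        rows.append(b.sequence)
        spans = {
            "tm": (tm_start, tm_end),
            "linker": (linker_start, linker_end),
            "motif": motif_span,
            "pipk": pipk_span,
        }
    return rows, spans


# ---------------------------------------------------------------------------
# family simulation under WAG (for the tree protocol)


@dataclass
class FamilySimSpec:
    """A sequence family evolved along a known tree under WAG."""

    tree: str | TreeNode
    root_sequence_length: int = 200
    indel_rate: float = 0.0
    seed: int = 0

    def resolved_tree(self) -> TreeNode:
        tree = (parse_newick(self.tree) if isinstance(self.tree, str)
                else self.tree)
        leaves = tree.leaf_names()
        if len(leaves) < 3:
            raise ValueError("family simulation needs >= 3 taxa")
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf names")
        for node in tree.walk():
            if node.length < 0:
                raise ValueError("negative branch length")
        return tree


def simulate_family(
    spec: FamilySimSpec,
    model: WAGModel | None = None,
) -> tuple[list[ProteinRecord], TreeNode, dict[str, list[int]]]:
    """Evolve a protein family along a tree by Markov substitution.

    The root is drawn from the WAG equilibrium frequencies; each branch
    applies P(branch length). Insertions and deletions (optional, rate per
    site per unit length) create and remove tracked site identities, so the
    returned homology map (leaf -> site id per column) is exact.
    Deterministic per seed.
    """
    if model is None:
        model = default_model()
    tree = spec.resolved_tree()
    rng = np.random.default_rng(spec.seed)
    next_site = [spec.root_sequence_length]

    root_states = rng.choice(20, size=spec.root_sequence_length, p=model.pi)
    root_sites = list(range(spec.root_sequence_length))

    records: list[ProteinRecord] = []
    homology: dict[str, list[int]] = {}

    def descend(node: TreeNode, states: np.ndarray, sites: list[int]) -> None:
        if node.length > 0:
            p = model.transition_matrix(node.length)
            cum = p.cumsum(axis=1)
            u = rng.random(states.size)
            states = (u[:, None] > cum[states]).sum(axis=1)
            if spec.indel_rate > 0:
                p_event = 1.0 - np.exp(-spec.indel_rate * node.length)
                keep = rng.random(states.size) >= p_event
                states = states[keep]
                sites = [s for s, k in zip(sites, keep) if k]
                n_ins = rng.poisson(p_event * max(len(sites), 1))
                for _ in range(n_ins):
                    pos = int(rng.integers(0, len(sites) + 1))
                    aa = int(rng.choice(20, p=model.pi))
                    states = np.insert(states, pos, aa)
                    sites = sites[:pos] + [next_site[0]] + sites[pos:]
                    next_site[0] += 1
        if node.is_leaf:
            seq = "".join(AA[s] for s in states)
            records.append(ProteinRecord(id=node.name, seq=seq))
            homology[node.name] = list(sites)
        else:
            for child in node.children:
                descend(child, states.copy(), list(sites))

    descend(tree, root_states, root_sites)
    return records, tree, homology
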