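"""Position-specific scoring profiles for accessory-domain scanning.

Domain evidence (PIPK, TKL, INPP, AC, PDE, DEP, AP, FYVE, plus the
transporter/channel decoy families) comes from log-odds profiles built from
packaged seed alignments. Columns with a gap majority (> 50% gaps) are
dropped; remaining columns are Laplace-smoothed against a background and
turned into bit scores:

    score(col, aa) = log2( ((count + pc * bg_aa) / (n + pc)) / bg_aa )

Scanning slides the profile along a sequence, sums per-column scores, and
reports non-overlapping above-threshold windows best-first. Thresholds can
be calibrated empirically from composition-preserving shuffles of a
background sequence set, or default to a fixed fraction of the maximum
achievable score.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

#: Canonical residue order used for every matrix in the package.
AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

#: Fraction of the maximum achievable score used for packaged default
#: thresholds (comfortably above any shuffle score, far below a faithful
#: domain instance).
DEFAULT_THRESHOLD_FRACTION = 0.35

#: Profile names treated as decoy (non-GPCR membrane protein) evidence.
DECOY_PROFILES = ("TRANSPORTER", "CHANNEL")

#: Profile names treated as catalytic accessory domains of GPCR-bigrams.
CATALYTIC_PROFILES = ("PIPK", "TKL", "INPP", "AC", "PDE")

#: Conserved catalytic anchors of the PIPK domain: the DLGKS and MDYSL
#: catalytic motifs plus the dilysine (KK) activation-loop motif.
PIPK_ANCHORS = ("DLGKS", "MDYSL", "KK")


@dataclass
class ProfileModel:
    """A per-column log-odds scoring matrix for one domain family."""

    name: str
    log_odds: np.ndarray          # (length, 20) bits
    frequencies: np.ndarray       # (length, 20) smoothed column frequencies
    background: np.ndarray        # (20,)
    threshold: float
    anchors: tuple[str, ...] = ()
    #: offset (0-based, relative to profile start) of the activation-loop
    #: dianion/dilysine position, where the PIPK type I/II variant sits
    activation_offset: int | None = None

    @property
    def length(self) -> int:
        return int(self.log_odds.shape[0])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.log_odds.argmax(axis=1))


@dataclass(frozen=True)
class DomainHit:
    """A scored, located profile match (1-based inclusive coordinates)."""

    profile_name: str
    start: int
    end: int
    score: float
    empirical_p: float | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("hit start > end")
        if self.empirical_p is not None and not (0.0 <= self.empirical_p <= 1.0):
            raise ValueError("empirical_p outside [0, 1]")


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as residue indices; unknown residues get -1."""
    return np.array([AA_INDEX.get(a, -1) for a in sequence.upper()], dtype=int)


def build_profile(
    name: str,
    alignment: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    threshold: float | None = None,
    anchors: tuple[str, ...] = (),
) -> ProfileModel:
    """Build a log-odds profile from an aligned set of sequences.

    Columns with more than 50% gaps are dropped before counting; in the
    retained columns, gapped rows are simply not counted.
    """
    if not alignment:
        raise ValueError("empty seed alignment")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    lengths = {len(row) for row in alignment}
    if len(lengths) != 1:
        raise ValueError("ragged seed alignment")
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)

    n_rows = len(alignment)
    cols = []
    for j in range(lengths.pop()):
        column = [row[j] for row in alignment]
        n_gap = sum(1 for c in column if c in "-.")
        if n_gap / n_rows > 0.5:
            continue
        counts = np.zeros(20)
        for c in column:
            idx = AA_INDEX.get(c.upper())
            if idx is not None:
                counts[idx] += 1
        cols.append(counts)
    if not cols:
        raise ValueError("no columns retained from seed alignment")
    counts = np.vstack(cols)
    n = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount * background) / (n + pseudocount)
    log_odds = np.log2(freqs / background)
    model = ProfileModel(
        name=name,
        log_odds=log_odds,
        frequencies=freqs,
        background=background,
        threshold=0.0,
        anchors=anchors,
    )
    model.threshold = (
        threshold if threshold is not None
        else DEFAULT_THRESHOLD_FRACTION * model.max_score
    )
    return model


def window_scores(sequence: str, profile: ProfileModel) -> np.ndarray:
    """Score every full window of profile length; unknown residues score 0."""
    enc = encode(sequence)
    n, L = enc.size, profile.length
    if n < L:
        return np.array([])
    scores = np.zeros(n - L + 1)
    for j in range(L):
        window = enc[j : j + n - L + 1]
        col = np.where(window >= 0, profile.log_odds[j, window], 0.0)
        scores += col
    return scores


def scan_profile(sequence: str, profile: ProfileModel) -> list[DomainHit]:
    """Report non-overlapping above-threshold hits, best score first.

    Greedy selection by score; ties broken by the smaller start position.
    """
    scores = window_scores(sequence, profile)
    if scores.size == 0:
        return []
    candidates = np.where(scores >= profile.threshold)[0]
    order = sorted(candidates, key=lambda i: (-scores[i], i))
    taken: list[tuple[int, int]] = []
    hits = []
    for i in order:
        start, end = i + 1, i + profile.length
        if any(not (end < s or start > e) for s, e in taken):
            continue
        taken.append((start, end))
        hits.append(DomainHit(profile.name, start, end, float(scores[i])))
    return hits


def calibrate_threshold(
    profile: ProfileModel,
    background_seqs: list[str],
    n_shuffles: int = 200,
    target_fpr: float = 0.01,
    seed: int = 0,
) -> float:
    """Empirical score threshold from composition-preserving shuffles.

    Each background sequence is Fisher-Yates shuffled ``n_shuffles`` times;
    the (1 - target_fpr) quantile of best-window scores becomes the
    threshold. Deterministic per seed.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not background_seqs:
        raise ValueError("no background sequences supplied")
    rng = np.random.default_rng(seed)
    best_scores = []
    for _ in range(n_shuffles):
        for seq in background_seqs:
            letters = np.array(list(seq))
            rng.shuffle(letters)
            scores = window_scores("".join(letters), profile)
            if scores.size:
                best_scores.append(scores.max())
    best = np.array(best_scores)
    if target_fpr <= 0:
        return float(best.max())
    return float(np.quantile(best, 1.0 - target_fpr, method="higher"))


def find_catalytic_anchors(
    sequence: str,
    hit: DomainHit,
    anchors: tuple[str, ...] = PIPK_ANCHORS,
    max_mismatch: int = 0,
) -> dict[str, bool]:
    """Check for short literal anchor motifs inside a domain hit.

    An anchor is present iff some substring of the hit span matches it with
    at most ``max_mismatch`` substitutions (Hamming distance).
    """
    if hit.end > len(sequence) or hit.start < 1:
        raise ValueError("hit outside sequence bounds")
    region = sequence[hit.start - 1 : hit.end]
    result = {}
    for anchor in anchors:
        k = len(anchor)
        found = False
        for i in range(len(region) - k + 1):
            mism = sum(1 for a, b in zip(region[i : i + k], anchor) if a != b)
            if mism <= max_mismatch:
                found = True
                break
        result[anchor] = found
    return result


# ---------------------------------------------------------------------------
# packaged seed alignments


def _data_dir() -> Path:
    return Path(resources.files("gpcrmine")) / "data"


def read_aligned_fasta(path: str | Path) -> list[str]:
    """Read an aligned FASTA file into a list of equal-length rows."""
    rows: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current:
                    rows.append("".join(current))
                current = []
            else:
                current.append(line)
    if current:
        rows.append("".join(current))
    return rows


def load_seed_alignment(name: str) -> list[str]:
    path = _data_dir() / "seed_alignments" / f"{name.lower()}.synthetic.afa"
    if not path.exists():
        raise FileNotFoundError(f"no packaged seed alignment for {name!r}")
    return read_aligned_fasta(path)


def load_default_profiles(pseudocount: float = 1.0) -> dict[str, ProfileModel]:
    """Build the packaged profile set from the shipped seed alignments."""
    directory = _data_dir() / "seed_alignments"
    profiles: dict[str, ProfileModel] = {}
    for path in sorted(directory.glob("*.synthetic.afa")):
        name = path.name.split(".")[0].upper()
        alignment = read_aligned_fasta(path)
        anchors = PIPK_ANCHORS if name == "PIPK" else ()
        model = build_profile(name, alignment, pseudocount=pseudocount,
                              anchors=anchors)
        if name == "PIPK":
            model.activation_offset = model.consensus.find("KK")
        profiles[name] = model
    return profiles


def serialize_profile(profile: ProfileModel, path: str | Path) -> None:
    """Write a profile as a TSV matrix with a small header block."""
    with open(path, "w") as fh:
        fh.write(f"#name\t{profile.name}\n")
        fh.write(f"#length\t{profile.length}\n")
        fh.write(f"#threshold\t{profile.threshold:.6f}\n")
        fh.write(f"#anchors\t{','.join(profile.anchors)}\n")
        fh.write("column\t" + "\t".join(AA) + "\n")
        for j in range(profile.length):
            row = "\t".join(f"{v:.6f}" for v in profile.log_odds[j])
            fh.write(f"{j + 1}\t{row}\n")
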