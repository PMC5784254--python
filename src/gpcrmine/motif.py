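"""Alignment conservation profiles and the LRxGI linker motif.

Between the receptor (7TM) region and the kinase domain of GPCR-PIPKs sits a
short, strongly conserved linker: 13 residues starting with a leucine-
arginine (LR) dimer, nine weakly constrained positions, and a terminal
glycine-isoleucine (GI) dimer -- the LRxGI motif, a hallmark of the family.

Conservation is scored per alignment column as the frequency of the
majority physico-chemical residue class among non-gap symbols (classes:
acidic, basic, hydrophobic, neutral, polar; partition shipped as package
configuration), then smoothed with a centered sliding moving average over 50
positions. At the profile edges the window truncates to the available
columns, so the smoothed series keeps the raw length.

The motif model is an anchored position weight matrix: literal LR/GI anchors
(zero mismatches by default -- the anchors are essentially invariant) plus a
9-column spacer scored by log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .profiles import AA, AA_INDEX, encode

ANCHOR_HEAD = "LR"
ANCHOR_TAIL = "GI"
SPACER_LENGTH = 9
MOTIF_LENGTH = len(ANCHOR_HEAD) + SPACER_LENGTH + len(ANCHOR_TAIL)

#: Fraction of the maximum achievable PWM score used as the default
#: match threshold.
# Just above the fraction the literal anchors alone can contribute (~0.33
# of the maximum), so a reported hit always needs positive spacer evidence.
DEFAULT_MOTIF_THRESHOLD_FRACTION = 0.35


def _data_path(name: str) -> Path:
    return Path(resources.files("gpcrmine")) / "data" / name


def load_residue_classes() -> dict[str, str]:
    """Residue -> physico-chemical class, from the packaged partition."""
    mapping: dict[str, str] = {}
    with open(_data_path("residue_classes.tsv")) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cls, residues = line.split("\t")
            for r in residues.strip():
                mapping[r] = cls
    return mapping


@dataclass
class ConservationProfile:
    """Per-column conservation in [0, 1] with a smoothed companion series."""

    raw: np.ndarray
    smoothed: np.ndarray | None = None
    window: int | None = None
    column_index: np.ndarray | None = None  # map to original alignment columns

    def __len__(self) -> int:
        return int(self.raw.size)


@dataclass
class MotifModel:
    """The anchored LRxGI model: LR + 9-column spacer + GI, 13 columns."""

    pwm: np.ndarray               # (13, 20) column frequencies
    log_odds: np.ndarray          # (13, 20) bits
    threshold: float
    anchor_head: str = ANCHOR_HEAD
    anchor_tail: str = ANCHOR_TAIL
    spacer_length: int = SPACER_LENGTH

    @property
    def total_length(self) -> int:
        return len(self.anchor_head) + self.spacer_length + len(self.anchor_tail)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def column_conservation(
    msa: list[str],
    residue_classes: dict[str, str] | None = None,
) -> ConservationProfile:
    """Majority-class conservation per column.

    score(col) = count of the most frequent residue class among non-gap
    symbols, divided by the non-gap count; an all-gap column scores 0.
    """
    if not msa:
        raise ValueError("empty alignment")
    if len({len(r) for r in msa}) != 1:
        raise ValueError("ragged alignment")
    classes = residue_classes or load_residue_classes()
    n_cols = len(msa[0])
    raw = np.zeros(n_cols)
    for j in range(n_cols):
        counts: dict[str, int] = {}
        n_nongap = 0
        for row in msa:
            c = row[j].upper()
            if c in "-.":
                continue
            n_nongap += 1
            cls = classes.get(c, "other")
            counts[cls] = counts.get(cls, 0) + 1
        raw[j] = max(counts.values()) / n_nongap if n_nongap else 0.0
    return ConservationProfile(raw=raw, column_index=np.arange(n_cols))


def smooth_profile(profile: ConservationProfile | np.ndarray,
                   window: int = 50) -> np.ndarray:
    """Centered moving mean; the window truncates at the edges.

    A window larger than the series simply returns the global mean at every
    position. Output length equals input length and stays in [0, 1].
    """
    raw = profile.raw if isinstance(profile, ConservationProfile) else np.asarray(profile, float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = raw.size
    if n == 0:
        return raw.copy()
    if window >= n:
        return np.full(n, raw.mean())
    kernel = np.ones(window)
    sums = np.convolve(raw, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    smoothed = sums / counts
    if isinstance(profile, ConservationProfile):
        profile.smoothed = smoothed
        profile.window = window
    return smoothed


def _consensus_residue(msa: list[str], col: int) -> str | None:
    counts: dict[str, int] = {}
    for row in msa:
        c = row[col].upper()
        if c in "-.":
            continue
        counts[c] = counts.get(c, 0) + 1
    if not counts:
        return None
    return max(sorted(counts), key=lambda k: counts[k])


def _column_frequencies(msa: list[str], cols: range | list[int],
                        pseudocount: float = 0.5) -> np.ndarray:
    pwm = np.zeros((len(cols), 20))
    for out_j, j in enumerate(cols):
        counts = np.zeros(20)
        for row in msa:
            idx = AA_INDEX.get(row[j].upper())
            if idx is not None:
                counts[idx] += 1
        pwm[out_j] = (counts + pseudocount / 20) / (counts.sum() + pseudocount)
    return pwm


def extract_linker_motif(
    msa: list[str],
    anchors: tuple[str, str] = (ANCHOR_HEAD, ANCHOR_TAIL),
    spacer_length: int = SPACER_LENGTH,
    pseudocount: float = 0.5,
    threshold_fraction: float = DEFAULT_MOTIF_THRESHOLD_FRACTION,
    conservation: ConservationProfile | None = None,
) -> MotifModel | None:
    """Extract the anchored 13-column motif model from a linker alignment.

    The chosen window maximises summed column conservation among windows
    whose anchor-column consensus spells the anchors (LR at the head, GI at
    the tail). Returns None when no anchored window exists.
    """
    if len(msa) < 5:
        raise ValueError("need at least 5 rows to model the linker motif")
    head, tail = anchors
    total = len(head) + spacer_length + len(tail)
    n_cols = len(msa[0])
    if n_cols < total:
        return None
    cons = conservation or column_conservation(msa)
    best_start, best_score = None, -np.inf
    for start in range(n_cols - total + 1):
        ok = True
        for k, aa in enumerate(head):
            if _consensus_residue(msa, start + k) != aa:
                ok = False
                break
        if ok:
            for k, aa in enumerate(tail):
                if _consensus_residue(msa, start + total - len(tail) + k) != aa:
                    ok = False
                    break
        if not ok:
            continue
        score = float(cons.raw[start : start + total].sum())
        if score > best_score:
            best_score, best_start = score, start
    if best_start is None:
        return None
    cols = list(range(best_start, best_start + total))
    pwm = _column_frequencies(msa, cols, pseudocount)
    log_odds = np.log2(pwm * 20.0)
    model = MotifModel(pwm=pwm, log_odds=log_odds, threshold=0.0)
    model.threshold = threshold_fraction * model.max_score
    model.window_start = best_start  # 0-based alignment column of the window
    return model


def build_default_motif_model(
    threshold_fraction: float = DEFAULT_MOTIF_THRESHOLD_FRACTION,
) -> MotifModel:
    """The packaged LRxGI model from the shipped spacer frequency table.

    Anchor columns put 0.92 of the mass on the anchor residue; the nine
    spacer columns come from the packaged spacer frequency table.
    """
    spacer = load_spacer_frequencies()
    pwm = np.zeros((MOTIF_LENGTH, 20))

    def anchor_column(aa: str) -> np.ndarray:
        col = np.full(20, (1.0 - 0.92) / 19)
        col[AA_INDEX[aa]] = 0.92
        return col

    for k, aa in enumerate(ANCHOR_HEAD):
        pwm[k] = anchor_column(aa)
    pwm[len(ANCHOR_HEAD) : len(ANCHOR_HEAD) + SPACER_LENGTH] = spacer
    for k, aa in enumerate(ANCHOR_TAIL):
        pwm[len(ANCHOR_HEAD) + SPACER_LENGTH + k] = anchor_column(aa)
    log_odds = np.log2(pwm * 20.0)
    model = MotifModel(pwm=pwm, log_odds=log_odds, threshold=0.0)
    model.threshold = threshold_fraction * model.max_score
    return model


def load_spacer_frequencies() -> np.ndarray:
    """(9, 20) spacer column frequencies from the packaged table."""
    rows = []
    with open(_data_path("lrxgi_spacer_frequencies.tsv")) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts[1:]
                continue
            rows.append([float(x) for x in parts[1:]])
    freqs = np.array(rows)
    order = [header.index(a) for a in AA]
    freqs = freqs[:, order]
    return freqs / freqs.sum(axis=1, keepdims=True)


def scan_motif(
    sequence: str,
    model: MotifModel,
    max_anchor_mismatch: int = 0,
) -> list[tuple[int, float]]:
    """Find motif hits: literal anchors plus an above-threshold PWM score.

    Returns (1-based start, score) pairs, best score first. Sequences
    shorter than the motif yield no hits.
    """
    total = model.total_length
    if len(sequence) < total:
        return []
    enc = encode(sequence)
    n = enc.size
    scores = np.zeros(n - total + 1)
    for j in range(total):
        window = enc[j : j + n - total + 1]
        scores += np.where(window >= 0, model.log_odds[j, window], 0.0)
    head, tail = model.anchor_head, model.anchor_tail
    hits = []
    for i in range(scores.size):
        if scores[i] < model.threshold:
            continue
        window = sequence[i : i + total].upper()
        mism = sum(1 for a, b in zip(window, head) if a != b)
        mism += sum(
            1 for a, b in zip(window[total - len(tail):], tail) if a != b
        )
        if mism <= max_anchor_mismatch:
            hits.append((i + 1, float(scores[i])))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def motif_present(
    sequence: str,
    model: MotifModel,
    region: tuple[int, int] | None = None,
    max_anchor_mismatch: int = 0,
) -> bool:
    """Presence flag; restricted to a 1-based inclusive region if given."""
    hits = scan_motif(sequence, model, max_anchor_mismatch)
    if region is None:
        return bool(hits)
    lo, hi = region
    return any(lo <= start and start + model.total_length - 1 <= hi
               for start, _ in hits)
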