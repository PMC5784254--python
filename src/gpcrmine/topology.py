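"""Transmembrane topology prediction by Kyte-Doolittle hydropathy.

A GPCR is recognised first by its membrane topology: seven membrane-spanning
helices with an extracellular N terminus and an intracellular C terminus.
This module scores sequences with a sliding-window hydropathy average,
calls maximal above-threshold runs as TM segments, orients the topology with
the positive-inside rule (cytoplasmic loops are enriched in K/R), and applies
the 5-9 TM candidate band used to pre-select receptor-like proteins.

Defaults (window 19, threshold 1.6, minimum helix length 15) are the
classical Kyte-Doolittle settings for membrane-spanning helices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Kyte-Doolittle hydropathy scale. Ambiguous residues (B, Z, X, U, O, J)
#: contribute 0 so that real-world FASTA dialects never raise.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

EXTRACELLULAR = "extracellular"
INTRACELLULAR = "intracellular"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class TMSegment:
    """One predicted membrane-spanning segment, 1-based inclusive."""

    start: int
    end: int
    mean_hydropathy: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, start: int, end: int) -> int:
        """Number of residues shared with [start, end] (1-based inclusive)."""
        return max(0, min(self.end, end) - max(self.start, start) + 1)


@dataclass(frozen=True)
class TMParams:
    window: int = 19
    threshold: float = 1.6
    min_helix_len: int = 15
    min_gap: int = 4

    def __post_init__(self):
        if self.window % 2 == 0 or not (5 <= self.window <= 31):
            raise ValueError("window must be odd and within [5, 31]")
        if self.min_helix_len < 1 or self.min_gap < 0:
            raise ValueError("invalid segment parameters")


@dataclass
class TopologyModel:
    """Ordered TM segments plus orientation and candidate flags."""

    segments: list[TMSegment]
    n_terminus_side: str = UNDETERMINED
    signal_peptide: TMSegment | None = None

    @property
    def n_tm(self) -> int:
        return len(self.segments)

    @property
    def is_7tm(self) -> bool:
        return self.n_tm == 7

    @property
    def passes_5to9_filter(self) -> bool:
        return 5 <= self.n_tm <= 9


def _encode_hydropathy(sequence: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in sequence.upper()])


def hydropathy_profile(sequence: str, window: int = 19) -> np.ndarray:
    """Centered sliding-window mean hydropathy.

    Returns an array the length of the sequence; positions whose window does
    not fit entirely inside the sequence carry ``nan`` (no score). A sequence
    shorter than the window yields an empty array.
    """
    if window % 2 == 0 or not (5 <= window <= 31):
        raise ValueError("window must be odd and within [5, 31]")
    n = len(sequence)
    if n < window:
        return np.array([])
    values = _encode_hydropathy(sequence)
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    half = window // 2
    out = np.full(n, np.nan)
    out[half : n - half] = means
    return out


def predict_tm_segments(sequence: str, params: TMParams = TMParams()) -> list[TMSegment]:
    """Call TM segments as maximal above-threshold runs of window scores.

    Runs separated by fewer than ``min_gap`` unscored-or-below positions are
    merged, then runs shorter than ``min_helix_len`` are dropped. Output is
    sorted and non-overlapping by construction.
    """
    profile = hydropathy_profile(sequence, params.window)
    if profile.size == 0:
        return []
    above = np.where(np.nan_to_num(profile, nan=-np.inf) > params.threshold)[0]
    if above.size == 0:
        return []
    # maximal runs of consecutive above-threshold positions
    runs: list[list[int]] = []
    run_start = above[0]
    prev = above[0]
    for idx in above[1:]:
        if idx == prev + 1:
            prev = idx
            continue
        runs.append([run_start, prev])
        run_start = prev = idx
    runs.append([run_start, prev])
    # merge runs separated by < min_gap
    merged: list[list[int]] = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] - 1 < params.min_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    values = _encode_hydropathy(sequence)
    segments = []
    for start, end in merged:
        if end - start + 1 >= params.min_helix_len:
            segments.append(
                TMSegment(
                    start=start + 1,
                    end=end + 1,
                    mean_hydropathy=float(values[start : end + 1].mean()),
                )
            )
    return segments


def detect_signal_peptide(
    sequence: str,
    search_span: int = 30,
    window: int = 7,
    threshold: float = 2.0,
    max_len: int = 17,
    min_len: int = 6,
) -> TMSegment | None:
    """Flag a short N-terminal hydrophobic stretch below TM helix length.

    Signal peptides present as a hydrophobic core of roughly 6-14 residues
    within the first ~30 positions -- too short to be called by the TM
    segment caller but hydrophobic enough to matter for the secreted-domain
    (AP-GPCR) architecture. Returns the stretch or None.
    """
    prefix = sequence[: search_span + window]
    profile = hydropathy_profile(prefix, window)
    if profile.size == 0:
        return None
    above = np.nan_to_num(profile, nan=-np.inf) > threshold
    best = None
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            # expand run to residue bounds of the small window
            start, end = i - window // 2, j + window // 2
            start = max(start, 0)
            length = end - start + 1
            if min_len <= length <= max_len and start < search_span:
                values = _encode_hydropathy(sequence[start : end + 1])
                cand = TMSegment(start + 1, end + 1, float(values.mean()))
                if best is None or cand.length > best.length:
                    best = cand
            i = j + 1
        else:
            i += 1
    return best


def build_topology(
    segments: list[TMSegment],
    sequence: str,
    charges_policy: str = "positive_inside",
    exclude_signal: bool = False,
    min_helix_len: int = 15,
) -> TopologyModel:
    """Assemble a topology model and orient it by the positive-inside rule.

    Loops alternate between the two membrane faces; the summed K+R count of
    each face is compared and the N terminus is assigned to the *less*
    positive face (cytoplasmic loops carry the positive charge). With
    ``exclude_signal`` a first segment that starts within the first 30
    residues and is shorter than ``min_helix_len + 5`` is treated as a
    signal-peptide candidate and removed from the TM count.
    """
    segments = sorted(segments, key=lambda s: s.start)
    signal = None
    if exclude_signal and segments:
        first = segments[0]
        if first.start <= 30 and first.length < min_helix_len + 5:
            signal = first
            segments = segments[1:]
    if not segments:
        return TopologyModel(segments=[], n_terminus_side=UNDETERMINED,
                             signal_peptide=signal)

    if charges_policy != "positive_inside":
        raise ValueError(f"unknown charges policy: {charges_policy}")

    # loops on the N-terminal face: N-tail, then every second inter-TM loop
    def positive_count(s: str) -> int:
        return s.count("K") + s.count("R")

    loops: list[str] = []
    loops.append(sequence[: segments[0].start - 1])
    for a, b in zip(segments, segments[1:]):
        loops.append(sequence[a.end : b.start - 1])
    loops.append(sequence[segments[-1].end :])

    n_side = sum(positive_count(l) for l in loops[0::2])
    other_side = sum(positive_count(l) for l in loops[1::2])
    if n_side < other_side:
        orientation = EXTRACELLULAR
    elif n_side > other_side:
        orientation = INTRACELLULAR
    else:
        orientation = UNDETERMINED
    return TopologyModel(segments=segments, n_terminus_side=orientation,
                         signal_peptide=signal)


def predict_topology(
    sequence: str,
    params: TMParams = TMParams(),
    exclude_signal: bool = False,
) -> TopologyModel:
    """Convenience: segments + assembly in one call."""
    segments = predict_tm_segments(sequence, params)
    model = build_topology(
        segments, sequence, exclude_signal=exclude_signal,
        min_helix_len=params.min_helix_len,
    )
    if model.signal_peptide is None:
        model.signal_peptide = detect_signal_peptide(sequence)
    return model


def is_gpcr_candidate(topology: TopologyModel, strict7: bool = False) -> bool:
    """The receptor candidate filter.

    Lenient mode keeps every protein with 5-9 predicted TM segments, the
    band used to pre-select receptor-like proteins; strict mode additionally
    demands the canonical 7TM topology with an extracellular N terminus.
    """
    if not topology.passes_5to9_filter:
        return False
    if strict7:
        return topology.is_7tm and topology.n_terminus_side == EXTRACELLULAR
    return True
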