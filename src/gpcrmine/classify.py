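"""The GPCR-bigram architecture grammar.

A bigram is a protein with a receptor (7TM) region and a catalytic
accessory domain in a fixed order. Six classes are called: GPCR-PIPK,
GPCR-TKL (optionally DEP-bearing), GPCR-INPP, GPCR-AC, GPCR-PDE, and the
mirror-image AP-GPCR (N-terminal secreted aspartic protease, C-terminal
receptor). Non-receptor membrane proteins (transporters, channels) are
discarded by decoy profile evidence or by a TM count outside the 5-9
candidate band; proteins without membrane segments are soluble.

PIPKs are additionally typed I-IV: the receptor-fused architecture defines
type IV, while soluble kinases are typed by a configurable signature table
(packaged defaults: a FYVE-like accessory marks type III; types I and II
are told apart by the activation-loop anchor variant). The defaults are
deliberately provisional configuration, not biology carved in stone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .profiles import CATALYTIC_PROFILES, DECOY_PROFILES, DomainHit, ProfileModel
from .topology import TopologyModel

# the six bigram classes
GPCR_PIPK = "GPCR_PIPK"
GPCR_TKL = "GPCR_TKL"
GPCR_INPP = "GPCR_INPP"
GPCR_AC = "GPCR_AC"
GPCR_PDE = "GPCR_PDE"
AP_GPCR = "AP_GPCR"
# non-bigram verdicts
GPCR_PLAIN = "GPCR_PLAIN"
NON_GPCR_TM = "NON_GPCR_TM"
SOLUBLE = "SOLUBLE"
AMBIGUOUS_TRUNCATED = "AMBIGUOUS_TRUNCATED"

BIGRAM_CLASSES = (GPCR_PIPK, GPCR_TKL, GPCR_INPP, GPCR_AC, GPCR_PDE, AP_GPCR)
ALL_CLASSES = BIGRAM_CLASSES + (GPCR_PLAIN, NON_GPCR_TM, SOLUBLE,
                                AMBIGUOUS_TRUNCATED)

PIPK_TYPES = ("I", "II", "III", "IV")

_CATALYTIC_TO_CLASS = {
    "PIPK": GPCR_PIPK,
    "TKL": GPCR_TKL,
    "INPP": GPCR_INPP,
    "AC": GPCR_AC,
    "PDE": GPCR_PDE,
}

#: maximum loop length (residues) between consecutive TM segments of one
#: receptor block -- prevents calling a "7TM" scattered over a huge protein
MAX_BLOCK_LOOP = 120


@dataclass
class ArchitectureCall:
    """The bigram-class verdict for one protein, with its evidence."""

    protein_id: str
    class_label: str
    has_dep: bool = False
    reconstituted: bool = False
    unresolved: bool = False
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.class_label not in ALL_CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.has_dep and self.class_label != GPCR_TKL:
            raise ValueError("has_dep is only meaningful for GPCR_TKL")

    @property
    def species(self) -> str:
        if "|" in self.protein_id:
            return self.protein_id.split("|", 1)[0]
        return "unknown"

    @property
    def is_bigram(self) -> bool:
        return self.class_label in BIGRAM_CLASSES


@dataclass(frozen=True)
class PIPKTypeCall:
    protein_id: str
    pipk_type: str  # I, II, III, IV or "ambiguous"


def _receptor_block(topology: TopologyModel) -> tuple[int, int] | None:
    """Largest run of consecutive TM segments with loops < MAX_BLOCK_LOOP.

    Returns (first_start, last_end) in residue coordinates, or None when no
    run of 5-9 adjacent segments exists. Seven adjacent helices is the
    canonical receptor; the 5-9 band matches the candidate filter and keeps
    borderline helix calls from breaking the class.
    """
    segs = topology.segments
    if not segs:
        return None
    runs: list[list] = [[segs[0]]]
    for prev, cur in zip(segs, segs[1:]):
        if cur.start - prev.end - 1 < MAX_BLOCK_LOOP:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    best = max(runs, key=len)
    if not (5 <= len(best) <= 9):
        return None
    return best[0].start, best[-1].end


def classify_architecture(
    protein_id: str,
    topology: TopologyModel,
    hits: list[DomainHit],
    motif_present: bool = False,
) -> ArchitectureCall:
    """Apply the architecture grammar to one protein.

    Decision order: decoy evidence / TM count outside 5-9 first; then a
    receptor block with a downstream catalytic hit; then the mirrored
    AP-GPCR geometry (signal peptide + AP domain N-terminal of a C-terminal
    receptor block); a passing topology without catalytic evidence is a
    plain receptor; a catalytic hit on a partial topology with motif
    evidence marks a probably-truncated gene model.
    """
    hits = sorted(hits, key=lambda h: h.start)
    decoy_hits = [h for h in hits if h.profile_name in DECOY_PROFILES]
    catalytic = [h for h in hits if h.profile_name in CATALYTIC_PROFILES]
    evidence = {
        "n_tm": topology.n_tm,
        "hits": hits,
        "motif": motif_present,
    }

    def call(label, **kw):
        return ArchitectureCall(protein_id, label, evidence=evidence, **kw)

    if decoy_hits:
        return call(NON_GPCR_TM if topology.n_tm > 0 else SOLUBLE)
    if not topology.passes_5to9_filter:
        if catalytic and motif_present:
            return call(AMBIGUOUS_TRUNCATED)
        return call(SOLUBLE if topology.n_tm == 0 else NON_GPCR_TM)

    block = _receptor_block(topology)
    if block is None:
        return call(NON_GPCR_TM)
    block_start, block_end = block
    evidence["block"] = block

    downstream = [h for h in catalytic if h.start > block_end]
    if downstream:
        # contradictory overlapping hits: higher score wins, then earlier start
        best = sorted(downstream, key=lambda h: (-h.score, h.start))[0]
        label = _CATALYTIC_TO_CLASS[best.profile_name]
        has_dep = label == GPCR_TKL and any(
            h.profile_name == "DEP" and h.start > best.end for h in hits
        )
        return call(label, has_dep=has_dep)

    ap_hits = [h for h in hits
               if h.profile_name == "AP" and h.end < block_start]
    if ap_hits and topology.signal_peptide is not None:
        return call(AP_GPCR)

    return call(GPCR_PLAIN)


def load_type_signatures() -> dict:
    path = Path(resources.files("gpcrmine")) / "data" / "pipk_type_signatures.yaml"
    with open(path) as fh:
        return yaml.safe_load(fh)


def classify_pipk_type(
    protein_id: str,
    hits: list[DomainHit],
    topology: TopologyModel,
    sequence: str,
    pipk_profile: ProfileModel | None = None,
    signatures: dict | None = None,
) -> PIPKTypeCall:
    """Type a PIPK-domain protein as I, II, III, IV or ambiguous.

    A receptor block preceding the kinase domain defines type IV. Soluble
    kinases are typed by the signature table: a FYVE-like accessory domain
    marks type III; otherwise the dipeptide at the activation-loop anchor
    position of the kinase profile separates types I and II. No match (or
    a truncated model without context) is ambiguous.
    """
    pipk_hits = [h for h in hits if h.profile_name == "PIPK"]
    if not pipk_hits:
        raise ValueError("no PIPK hit: cannot type")
    signatures = signatures or load_type_signatures()
    block = _receptor_block(topology)
    pipk = sorted(pipk_hits, key=lambda h: (-h.score, h.start))[0]
    if block is not None and pipk.start > block[1]:
        return PIPKTypeCall(protein_id, "IV")

    accessory = signatures.get("III", {}).get("accessory_profile")
    if accessory and any(h.profile_name == accessory for h in hits):
        return PIPKTypeCall(protein_id, "III")

    if pipk_profile is not None and pipk_profile.activation_offset is not None:
        pos = pipk.start - 1 + pipk_profile.activation_offset
        dipeptide = sequence[pos : pos + 2]
        for t in ("I", "II"):
            if dipeptide == signatures.get(t, {}).get("activation_anchor"):
                return PIPKTypeCall(protein_id, t)
    return PIPKTypeCall(protein_id, "ambiguous")


# ---------------------------------------------------------------------------
# fragment reconstitution


def _overlap_length(a_seq: str, b_seq: str, max_overlap: int = 30) -> int:
    """Longest suffix of a that equals a prefix of b (up to max_overlap)."""
    limit = min(len(a_seq), len(b_seq), max_overlap)
    for k in range(limit, 0, -1):
        if a_seq[-k:] == b_seq[:k]:
            return k
    return 0


def reconstitute_fragments(
    records: dict[str, str],
    calls: list[ArchitectureCall],
    motif_hits: dict[str, list[tuple[int, float]]],
    min_overlap: int = 5,
    motif_tail_window: int = 60,
) -> list[ArchitectureCall]:
    """Pair truncated gene models into merged receptor-kinase candidates.

    A record carrying a receptor block plus the linker motif (but no kinase
    domain) is paired with a same-species record carrying a kinase domain
    (but no receptor block). Pairing needs either a sequence overlap of at
    least ``min_overlap`` residues or motif adjacency: the motif near the
    first fragment's C terminus and the kinase domain near the second
    fragment's N terminus. The best overlap wins; exact ties are reported
    for every partner, flagged unresolved.
    """
    by_id = {c.protein_id: c for c in calls}

    def has_pipk(call: ArchitectureCall) -> bool:
        return any(h.profile_name == "PIPK" for h in call.evidence.get("hits", []))

    heads = [
        c for c in calls
        if c.class_label == GPCR_PLAIN
        and c.evidence.get("motif")
        and not has_pipk(c)
    ]
    tails = [
        c for c in calls
        if c.class_label in (SOLUBLE, AMBIGUOUS_TRUNCATED, NON_GPCR_TM)
        and "block" not in c.evidence
        and has_pipk(c)
    ]

    merged: list[ArchitectureCall] = []
    for head in heads:
        candidates = []
        head_seq = records[head.protein_id]
        for tail in tails:
            if tail.species != head.species:
                continue
            tail_seq = records[tail.protein_id]
            overlap = _overlap_length(head_seq, tail_seq)
            adjacency = False
            hits = motif_hits.get(head.protein_id, [])
            if hits:
                last_motif_end = max(s for s, _ in hits) + 12
                pipk = min(
                    (h.start for h in tail.evidence["hits"]
                     if h.profile_name == "PIPK"),
                    default=None,
                )
                adjacency = (
                    len(head_seq) - last_motif_end <= motif_tail_window
                    and pipk is not None
                    and pipk <= motif_tail_window
                )
            if overlap >= min_overlap or adjacency:
                candidates.append((overlap, tail))
        if not candidates:
            continue
        best_overlap = max(o for o, _ in candidates)
        winners = [t for o, t in candidates if o == best_overlap]
        for tail in winners:
            merged.append(
                ArchitectureCall(
                    protein_id=f"{head.protein_id}+{tail.protein_id}",
                    class_label=GPCR_PIPK,
                    reconstituted=True,
                    unresolved=len(winners) > 1,
                    evidence={
                        "members": (head.protein_id, tail.protein_id),
                        "overlap": best_overlap,
                    },
                )
            )
    return merged


# ---------------------------------------------------------------------------
# inventories


def inventory(calls: list[ArchitectureCall]) -> pd.DataFrame:
    """Per-species x class count table with a totals row.

    Classes appear as columns in canonical order; absent classes show 0.
    """
    columns = list(ALL_CLASSES)
    species = sorted({c.species for c in calls})
    table = pd.DataFrame(0, index=species, columns=columns, dtype=int)
    for call in calls:
        table.loc[call.species, call.class_label] += 1
    table.loc["total"] = table.sum(axis=0)
    return table
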