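"""Pipeline orchestration: simulate -> topology -> scan -> classify ->
motif -> phylogeny, with one seed, stage-count accounting and TSV artifacts.

Every stage is a thin composition of the library modules; the run report
keeps per-stage record counts in the style of a search-strategy flowchart
(total models, TM-containing, 5-9 TM candidates, receptor candidates after
decoy removal, bigrams), so a run can be audited at a glance.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path


import pandas as pd
import yaml

from . import classify as cls
from . import motif as motif_mod
from . import phylo, profiles, synthetic, topology
from .records import ProteinRecord, read_fasta, write_fasta


@dataclass
class PipelineConfig:
    """All knobs of a run; one seed drives every stochastic stage."""

    seed: int = 42
    output_dir: str = "results"
    input_fasta: str | None = None
    # simulation
    preset: str = "pinf_like"
    species: str = "Pinfsim"
    # topology
    tm_window: int = 19
    tm_threshold: float = 1.6
    min_helix_len: int = 15
    min_gap: int = 4
    strict7: bool = False
    # scanning
    pseudocount: float = 1.0
    # motif
    motif_window: int = 50
    motif_threshold_fraction: float = motif_mod.DEFAULT_MOTIF_THRESHOLD_FRACTION
    # phylogeny
    trim_max_gap_fraction: float = 0.25
    bootstrap_replicates: int = 100
    gamma_shape: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.trim_max_gap_fraction <= 1.0):
            raise ValueError("trim fraction must lie in [0, 1]")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap replicates must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_yaml(cls_, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls_(**data)

    def tm_params(self) -> topology.TMParams:
        return topology.TMParams(
            window=self.tm_window, threshold=self.tm_threshold,
            min_helix_len=self.min_helix_len, min_gap=self.min_gap,
        )

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage record counts plus bookkeeping."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    wall_clock_s: float = 0.0
    seed: int | None = None
    spec_hash: str | None = None

    def count(self, stage: str, n: int) -> None:
        self.stage_counts[stage] = int(n)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "stage_counts": self.stage_counts,
                    "warnings": self.warnings,
                    "wall_clock_s": round(self.wall_clock_s, 3),
                    "seed": self.seed,
                    "spec_hash": self.spec_hash,
                },
                fh, indent=2,
            )
            fh.write("\n")


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: PipelineConfig
                 ) -> tuple[list[ProteinRecord], synthetic.GroundTruth]:
    """Generate the configured synthetic proteome and write its artifacts."""
    if config.preset == "pinf_like":
        specs, n_background = synthetic.pinf_like_specs()
    elif config.preset == "empty":
        specs, n_background = [], 5
    else:
        raise ValueError(f"unknown preset {config.preset!r}")
    records, truth = synthetic.generate_proteome(
        specs, n_background, seed=config.seed, species=config.species)
    out = _outdir(config)
    write_fasta(records, out / "proteome.fasta")
    truth.to_tsv(out / "truth.tsv")
    manifest = {
        "seed": config.seed,
        "preset": config.preset,
        "spec_hash": config.spec_hash(),
        "n_records": len(records),
        "n_bigrams_planted": truth.n_bigrams(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return records, truth


def scan_all(
    records: list[ProteinRecord],
    profile_set: dict[str, profiles.ProfileModel],
) -> dict[str, list[profiles.DomainHit]]:
    return {
        r.id: sorted(
            (h for p in profile_set.values()
             for h in profiles.scan_profile(r.seq, p)),
            key=lambda h: h.start,
        )
        for r in records
    }


def run_inventory(
    config: PipelineConfig,
    records: list[ProteinRecord] | None = None,
) -> tuple[list[cls.ArchitectureCall], pd.DataFrame, RunReport]:
    """Topology -> decoy/TM filter -> domain scan -> classify -> inventory."""
    t0 = time.time()
    report = RunReport(seed=config.seed, spec_hash=config.spec_hash())
    if records is None:
        if config.input_fasta is None:
            raise ValueError("no input records: set input_fasta or simulate")
        records = read_fasta(config.input_fasta)
    out = _outdir(config)
    report.count("records", len(records))

    params = config.tm_params()
    topologies = {r.id: topology.predict_topology(r.seq, params)
                  for r in records}
    report.count("with_tm", sum(1 for t in topologies.values() if t.n_tm > 0))
    report.count(
        "candidates_5to9",
        sum(1 for t in topologies.values()
            if topology.is_gpcr_candidate(t, strict7=config.strict7)),
    )

    profile_set = profiles.load_default_profiles(pseudocount=config.pseudocount)
    hits = scan_all(records, profile_set)
    motif_model = motif_mod.build_default_motif_model(
        config.motif_threshold_fraction)
    motif_hits = {r.id: motif_mod.scan_motif(r.seq, motif_model)
                  for r in records}

    calls = [
        cls.classify_architecture(
            r.id, topologies[r.id], hits[r.id],
            motif_present=bool(motif_hits[r.id]),
        )
        for r in records
    ]
    n_receptor = sum(1 for c in calls
                     if c.class_label not in (cls.NON_GPCR_TM, cls.SOLUBLE))
    report.count("receptor_like_after_decoy_filter", n_receptor)
    report.count("bigrams", sum(1 for c in calls if c.is_bigram))

    # artifacts
    topo_rows = []
    for r in records:
        t = topologies[r.id]
        topo_rows.append({
            "protein_id": r.id,
            "n_tm": t.n_tm,
            "coords": ",".join(f"{s.start}-{s.end}" for s in t.segments),
            "orientation": t.n_terminus_side,
            "is_7tm": t.is_7tm,
            "passes_5to9": t.passes_5to9_filter,
        })
    pd.DataFrame(topo_rows).to_csv(out / "topology.tsv", sep="\t", index=False)

    hit_rows = [
        {"protein_id": pid, "profile": h.profile_name, "start": h.start,
         "end": h.end, "score": round(h.score, 3),
         "empirical_p": "" if h.empirical_p is None else h.empirical_p}
        for pid, hs in hits.items() for h in hs
    ]
    pd.DataFrame(hit_rows, columns=["protein_id", "profile", "start", "end",
                                    "score", "empirical_p"]
                 ).to_csv(out / "hits.tsv", sep="\t", index=False)

    call_rows = [
        {"protein_id": c.protein_id, "class": c.class_label,
         "has_dep": c.has_dep, "n_tm": c.evidence.get("n_tm", ""),
         "motif": c.evidence.get("motif", False)}
        for c in calls
    ]
    pd.DataFrame(call_rows).to_csv(out / "calls.tsv", sep="\t", index=False)

    table = cls.inventory(calls)
    table.to_csv(out / "inventory.tsv", sep="\t")

    report.wall_clock_s = time.time() - t0
    report.to_json(out / "inventory_report.json")
    return calls, table, report


def extract_pipk_regions(
    records: list[ProteinRecord],
    hits: dict[str, list[profiles.DomainHit]],
) -> list[tuple[str, str]]:
    """Kinase-domain subsequences only -- the tree never sees full proteins."""
    regions = []
    for r in records:
        pipk = [h for h in hits.get(r.id, []) if h.profile_name == "PIPK"]
        if not pipk:
            continue
        best = sorted(pipk, key=lambda h: (-h.score, h.start))[0]
        regions.append((r.id, r.seq[best.start - 1 : best.end]))
    return regions


def run_pipk_workflow(
    config: PipelineConfig,
    records: list[ProteinRecord],
    calls: list[cls.ArchitectureCall] | None = None,
) -> dict:
    """Motif discovery + kinase-domain phylogeny over all PIPK carriers.

    Extracts kinase regions from every protein with a kinase-domain hit,
    aligns and trims them, builds the WAG/NJ tree with column bootstrap,
    and evaluates per-type monophyly (the receptor-fused kinases are type
    IV). In parallel, the linker regions of the receptor-kinase proteins are
    aligned, the anchored motif model extracted, and all records scanned
    for motif presence. Fewer than three kinase regions skips the tree with
    a warning rather than failing.
    """
    t0 = time.time()
    out = _outdir(config)
    result: dict = {"warnings": []}
    profile_set = profiles.load_default_profiles(pseudocount=config.pseudocount)
    hits = scan_all(records, profile_set)
    topologies = {r.id: topology.predict_topology(r.seq, config.tm_params())
                  for r in records}
    by_id = {r.id: r for r in records}

    type_calls = {}
    for r in records:
        if any(h.profile_name == "PIPK" for h in hits[r.id]):
            type_calls[r.id] = cls.classify_pipk_type(
                r.id, hits[r.id], topologies[r.id], r.seq,
                pipk_profile=profile_set["PIPK"],
            ).pipk_type
    result["pipk_types"] = type_calls

    # ---- linker motif from receptor-fused kinases
    linkers = []
    for r in records:
        if type_calls.get(r.id) != "IV":
            continue
        block = cls._receptor_block(topologies[r.id])
        pipk = [h for h in hits[r.id] if h.profile_name == "PIPK"]
        if block is None or not pipk:
            continue
        linker = r.seq[block[1] : pipk[0].start - 1]
        if linker:
            linkers.append((r.id, linker))
    motif_model = None
    if len(linkers) >= 5:
        linker_msa = phylo.progressive_align(linkers)
        motif_model = motif_mod.extract_linker_motif(
            linker_msa.rows,
            threshold_fraction=config.motif_threshold_fraction,
        )
    if motif_model is None:
        result["warnings"].append(
            "no anchored linker motif extracted; falling back to the "
            "packaged model")
        motif_model = motif_mod.build_default_motif_model(
            config.motif_threshold_fraction)
        result["motif_source"] = "packaged"
    else:
        result["motif_source"] = "extracted"
    result["motif_length"] = motif_model.total_length

    presence_rows = [
        {"protein_id": r.id,
         "motif_present": bool(motif_mod.scan_motif(r.seq, motif_model))}
        for r in records
    ]
    pd.DataFrame(presence_rows).to_csv(out / "motif_presence.tsv", sep="\t",
                                       index=False)
    result["motif_presence"] = {
        row["protein_id"]: row["motif_present"] for row in presence_rows
    }

    # ---- kinase-domain tree
    regions = extract_pipk_regions(records, hits)
    result["n_pipk_regions"] = len(regions)
    if len(regions) < 3:
        result["warnings"].append("fewer than 3 kinase regions: tree skipped")
        result["tree"] = None
        return result

    msa = phylo.progressive_align(regions)
    trimmed, kept = phylo.trim_gap_columns(msa, config.trim_max_gap_fraction)
    if trimmed.n_cols == 0:
        result["warnings"].append("all columns trimmed: tree skipped")
        result["tree"] = None
        return result
    tree, support = phylo.bootstrap_support(
        trimmed, n_replicates=config.bootstrap_replicates,
        seed=config.seed, gamma_shape=config.gamma_shape,
    )
    labels = {rid: type_calls.get(rid, "ambiguous") for rid, _ in regions}
    clades = phylo.evaluate_type_clades(tree, labels)
    result["tree"] = tree
    result["clades"] = clades

    with open(out / "pipk_tree.nwk", "w") as fh:
        fh.write(tree.to_newick() + "\n")
    clade_rows = [
        {"pipk_type": t, **{k: v for k, v in d.items()}}
        for t, d in clades.items()
    ]
    pd.DataFrame(clade_rows).to_csv(out / "type_clades.tsv", sep="\t",
                                    index=False)
    result["wall_clock_s"] = time.time() - t0
    return result


def run_all(config: PipelineConfig) -> dict:
    records, truth = run_simulate(config)
    calls, table, report = run_inventory(config, records)
    workflow = run_pipk_workflow(config, records, calls)
    return {
        "records": records,
        "truth": truth,
        "calls": calls,
        "inventory": table,
        "report": report,
        "pipk_workflow": workflow,
    }
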