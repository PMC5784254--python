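# gpcrmine

Mining proteomes for **GPCR-bigrams**: receptors that carry their own
catalytic domain.

G-protein-coupled receptors (GPCRs) are seven-transmembrane (7TM) proteins
with an extracellular N terminus and an intracellular C terminus; they
normally signal through heterotrimeric G proteins. Several unicellular
eukaryotes — oomycetes most prominently — instead encode *bigram*
receptors in which a 7TM region is fused directly to a catalytic accessory
domain: a phosphatidylinositol phosphate kinase (GPCR-PIPK), a tyrosine
kinase-like domain optionally followed by DEP (GPCR-TKL), an inositol
polyphosphate phosphatase (GPCR-INPP), an adenylyl cyclase (GPCR-AC), a
phosphodiesterase (GPCR-PDE), or — mirror-imaged — an N-terminal secreted
aspartic protease ahead of a C-terminal receptor (AP-GPCR). GPCR-PIPKs
additionally share a hallmark 13-residue linker motif between the receptor
and kinase regions, **LRxGI**: a conserved leucine–arginine dimer, nine
weakly constrained residues, and a glycine–isoleucine dimer. Their kinase
domains form a clade of their own (type IV) apart from the classical PIPK
types I–III.

`gpcrmine` is for computational biologists who want a transparent,
fully-tested implementation of the whole mining protocol, runnable end to
end on a laptop. Because the protocol is normally exercised against
proteome databases and annotation servers, the package ships a synthetic
proteome generator with planted, machine-readable ground truth, so every
stage is benchmarked without downloads.

## The method

1. **Topology.** Kyte–Doolittle hydropathy `h_i = mean(KD[s_{i-9}..s_{i+9}])`
   (window 19), TM segments as maximal runs with `h_i > 1.6` of length
   ≥ 15; orientation by the positive-inside rule; receptor candidates have
   5–9 TM segments.
2. **Domains.** Per-column log-odds profiles
   `S(j, a) = log2(((c_{ja} + bg_a) / (n_j + 1)) / bg_a)` built from seed
   alignments; gapless window scanning with greedy non-overlapping hits;
   decoy profiles (transporter/channel) drive the discard rule.
3. **Grammar.** Decoys and out-of-band TM counts out first; then a block of
   5–9 adjacent TM segments with a downstream catalytic hit names the
   class; signal peptide + protease ahead of a C-terminal block names
   AP-GPCR. Receptor-fused kinases are PIPK type IV; soluble kinases are
   typed I–III from a signature table. Split gene models (receptor+motif /
   kinase) are reconstituted by overlap or motif adjacency.
4. **Motif.** Class-based column conservation with a 50-position sliding
   average; the anchored 13-column LRxGI weight matrix is extracted from
   the linker alignment and scanned with literal anchors plus a log-odds
   threshold.
5. **Phylogeny.** Kinase-domain regions only: progressive Gotoh/BLOSUM62
   alignment, >25%-gap columns trimmed, pairwise maximum-likelihood
   distances under the WAG substitution model, neighbor joining, column
   bootstrap, per-type monophyly report.

Details, defaults and their rationale: [docs/methods.md](docs/methods.md).

## Worked example

Run the numbered analyses in order (each is a thin driver over the
library):

```
$ python analysis/01_simulate_proteome.py
generated 244 records (44 planted bigrams) with seed 42
...
$ python analysis/02_tm_topology.py
244 records; 144 with TM segments; 44 candidates with 5-9 TM
planted helix recovery: 1008/1008 (100.0%)

$ python analysis/04_classify_inventory.py
stage counts: {'records': 244, 'with_tm': 144, 'candidates_5to9': 44,
               'receptor_like_after_decoy_filter': 44, 'bigrams': 44}
         GPCR_PIPK  GPCR_TKL  GPCR_INPP  GPCR_AC  GPCR_PDE  AP_GPCR  ...
total           12        17          7        4         3        1  ...
bigrams called: 44 (planted 44); TKL 17, DEP-bearing 8, PIPK 12
false positives among decoys: 0

$ python analysis/06_pipk_phylogeny.py
kinase regions in tree: 52
type   I: 12 leaves, monophyletic=True, bootstrap 94%
type  II: 12 leaves, monophyletic=True, bootstrap 100%
type III: 16 leaves, monophyletic=True, bootstrap 86%
type  IV: 12 leaves, monophyletic=True, bootstrap 100%
```

Reading the numbers: of 244 generated proteins, 144 carry TM segments and
exactly the 44 planted bigrams survive the 5–9 TM band and the decoy
filter; the grammar then recovers the planted census class by class (12
receptor-kinases, 17 receptor-TKLs of which 8 DEP-bearing, …) with no
false positives among the 200 decoys. In the kinase-domain tree the
receptor-fused kinases (type IV) form their own fully supported clade,
distinct from the classical types — the family-level signature the
pipeline exists to detect. `analysis/05_linker_motif.py` additionally
shows the smoothed conservation profile of a divergent receptor-kinase
family peaking at the linker and the extracted 13-column LRxGI model
flagging all 12 planted receptor-kinases and nothing else.

The same stages are available as a CLI (`gpcrmine simulate|inventory|
pipk|all`, see `gpcrmine --help`) driven by an optional YAML config.

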