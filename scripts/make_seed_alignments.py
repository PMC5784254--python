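"""Regenerate the packaged synthetic seed alignments and config tables.

The seed alignments are synthetic fixtures: each domain family gets a
random hydrophilic consensus (so emitted domains never mimic membrane
helices), diverged per-row with 20% column noise and sparse gaps. The
kinase (PIPK) family embeds its three invariant catalytic anchors --
DLGKS, MDYSL and the activation-loop dilysine KK -- as near-invariant
columns. Run from the repository root:

    python scripts/make_seed_alignments.py
"""

from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parents[1] / "src" / "gpcrmine" / "data"
AA = "ACDEFGHIKLMNPQRSTVWY"

# hydrophilic-leaning alphabet for domain consensus sequences
SOLUBLE_ALPHABET = "ADEGHKNPQRSTWYC"

FAMILIES = {
    # name: (length, anchors embedded at fixed offsets)
    "pipk": (60, {8: "DLGKS", 28: "MDYSL", 46: "KK"}),
    "tkl": (50, {}),
    "inpp": (50, {}),
    "ac": (50, {}),
    "pde": (50, {}),
    "dep": (40, {}),
    "ap": (55, {}),
    "fyve": (40, {}),
    "transporter": (50, {}),
    "channel": (50, {}),
}

N_ROWS = 30
MUTATION_P = 0.20
ANCHOR_MUTATION_P = 0.02
GAP_P = 0.02


def make_consensus(rng, name, length, anchors):
    while True:
        cons = list("".join(rng.choice(list(SOLUBLE_ALPHABET), size=length)))
        anchor_cols = set()
        for off, motif in anchors.items():
            cons[off : off + len(motif)] = motif
            anchor_cols.update(range(off, off + len(motif)))
        text = "".join(cons)
        if name == "pipk" and text.count("KK") != 1:
            continue  # the activation dilysine must be unique
        return text, anchor_cols


def make_alignment(rng, name, length, anchors):
    consensus, anchor_cols = make_consensus(rng, name, length, anchors)
    rows = []
    for _ in range(N_ROWS):
        row = []
        for j, c in enumerate(consensus):
            p_mut = ANCHOR_MUTATION_P if j in anchor_cols else MUTATION_P
            if j not in anchor_cols and rng.random() < GAP_P:
                row.append("-")
            elif rng.random() < p_mut:
                row.append(rng.choice(list(SOLUBLE_ALPHABET)))
            else:
                row.append(c)
        rows.append("".join(row))
    return rows


def write_spacer_table(rng, path):
    dominants = "EAWKSLDQT"  # amphipathic mix: charged + hydrophobic
    with open(path, "w") as fh:
        fh.write("# LRxGI spacer column frequencies (9 columns x 20 residues)\n")
        fh.write("# synthetic defaults: the motif definition constrains only the\n")
        fh.write("# LR/GI anchors, so spacer composition is package config\n")
        fh.write("position\t" + "\t".join(AA) + "\n")
        for j, dom in enumerate(dominants):
            freqs = np.full(20, 0.1 / 17)
            others = [a for a in AA if a != dom]
            second = rng.choice(others, size=2, replace=False)
            for s in second:
                freqs[AA.index(s)] = 0.1
            freqs[AA.index(dom)] = 0.7
            freqs /= freqs.sum()
            fh.write(f"{j + 1}\t" + "\t".join(f"{v:.6f}" for v in freqs) + "\n")


def main():
    rng = np.random.default_rng(20180123)
    aln_dir = DATA / "seed_alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    for name, (length, anchors) in FAMILIES.items():
        rows = make_alignment(rng, name, length, anchors)
        path = aln_dir / f"{name}.synthetic.afa"
        with open(path, "w") as fh:
            for i, row in enumerate(rows):
                fh.write(f">{name}_synthetic_{i + 1:02d}\n{row}\n")
        print(f"wrote {path} ({N_ROWS} rows x {length} cols)")
    write_spacer_table(rng, DATA / "lrxgi_spacer_frequencies.tsv")
    print("wrote spacer frequency table")


if __name__ == "__main__":
    main()
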