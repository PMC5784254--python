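"""Predict transmembrane topologies for the benchmark proteome.

Runs the hydropathy scanner over results/proteome.fasta, reports how many
records carry TM segments and how many fall in the 5-9 TM receptor
candidate band, and checks detected helices against the planted truth.
"""

from gpcrmine.records import read_fasta
from gpcrmine.synthetic import GroundTruth
from gpcrmine.topology import is_gpcr_candidate, predict_topology


def main():
    records = read_fasta("results/proteome.fasta")
    truth = GroundTruth.from_tsv("results/truth.tsv")

    n_tm, n_candidates = 0, 0
    recovered, planted = 0, 0
    for r in records:
        topo = predict_topology(r.seq)
        n_tm += topo.n_tm > 0
        n_candidates += is_gpcr_candidate(topo)
        for s, e in truth[r.id].tm_segments:
            planted += 1
            if any(seg.overlap(s, e) >= 0.5 * (e - s + 1)
                   for seg in topo.segments):
                recovered += 1
    print(f"{len(records)} records; {n_tm} with TM segments; "
          f"{n_candidates} candidates with 5-9 TM")
    print(f"planted helix recovery: {recovered}/{planted} "
          f"({100 * recovered / planted:.1f}%)")


if __name__ == "__main__":
    main()
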