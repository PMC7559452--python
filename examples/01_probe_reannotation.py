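"""Reannotate microarray probes to a smORF and compute the overlap weight.

A probe set's signal is shared by whatever its probes cover. Here 4 of a
set's 10 probes land inside a smORF, so the smORF is credited with weight
4/10 = 0.4 of that probe set's signal. A second probe is planted in 100
tandem copies and is discarded as ambiguous before weighting.
"""

from smorfpred import GenomicInterval, Probe, SmORF, annotate_probe_sets, match_probe

# 10 distinct 10-nt probes laid end-to-end form the "genome"; the smORF
# covers the first 4 of them.
probe_seqs = [
    "ACGGTCATCA", "GGATACCTGT", "TTCAGCAGGA", "CATGGTGGAC", "GACCATTCAG",
    "TGGACCAATG", "CCTTGAGATC", "AGGATCCTTG", "GTCCTTGGAA", "CAACGGATTC",
]
genome = {"chr1": "".join(probe_seqs) + "ACGTTGCAAC" * 100}
probes = [Probe("ps_demo", f"p{i:02d}", seq) for i, seq in enumerate(probe_seqs)]
multi = Probe("ps_demo2", "p_multi", "ACGTTGCAAC")
smorf = SmORF("smorf_demo", GenomicInterval("chr1", 0, 40, "+"))

annotations, stats = annotate_probe_sets(probes + [multi], genome, [smorf])

print(f"probes read     : {stats['probes_read']}")
print(f"probes retained : {stats['probes_retained']}")
for a in annotations:
    print(f"annotation      : {a.probe_set_id} -> {a.smorf_id}, weight {a.weight}")
aln = match_probe(multi, genome)
print(f"tandem probe    : {len(aln.matches)} matches, retained={aln.retained}")

# The weight 0.4 means 4 of the set's 10 retained probes overlap the smORF
# by at least one base; the 100-copy probe fails the <100-matches rule, so
# its probe set contributes nothing.
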