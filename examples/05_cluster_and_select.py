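"""Filter, mask and cluster ESTs, then pick clones for full sequencing.

Reads lacking a >100-base run of quality >= 10 are discarded; poly(A)
tracts are masked; the greedy assembler groups overlapping reads into
contigs; the 5'-most member of each contig is the sequencing candidate,
plus singlets that hit genes no contig pick covers.
"""

import capmap as cm
from capmap.io_formats import SeqRecord

cfg = cm.SimConfig(seed=5, n_genes=10, n_reads=400)
genome, models, _ = cm.simulate_genome(cfg)
reads, quals, truth = cm.simulate_reads(genome, models, cfg)

kept = [(r, q) for r, q in zip(reads, quals) if cm.quality_filter(r, q)]
masked = [SeqRecord(r.id, r.description, cm.mask_low_complexity(r.sequence))
          for r, _ in kept]
contigs, singlets = cm.cluster_ests(masked)
dist = cm.contig_size_distribution(contigs)
gene_of = {rt.read_id: rt.gene_id for rt in truth.reads}
selection = cm.select_clones(contigs, singlets, gene_of,
                             {r.id: len(r.sequence) for r, _ in kept})

print(f"kept {len(kept)}/{len(reads)} reads after quality filtering")
print(f"{len(contigs)} contigs, {len(singlets)} singlets; "
      f"{dist['n_lt_20']} contigs carry <20 ESTs")
print(f"selected {len(selection.selected_from_contigs)} forefront clones "
      f"and {len(selection.selected_from_singlets)} novel-gene singlets")
# Forefront clones are the most-5' members of their contigs — the best
# candidates for carrying complete transcripts.
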