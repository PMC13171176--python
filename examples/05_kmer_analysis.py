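"""Score, rank and compare k-mers by their attribution.

Uses ground-truth attribution proxies from a two-cell-type synthetic pair
(per-base score = planted motif effect x local accessibility) to show the
k-mer machinery: instance scoring, per-k-mer tables, rank changes between
two tables, and the top-10% Jaccard comparison between cell types that do
or do not share active motifs.
"""

from chromexpr import experiments, kmers, synth

base = synth.SynthConfig(n_genes=300, L=300, seed=4, share_openness=True,
                         noise_sd=0.0)

pair_shared = synth.make_cell_type_pair(base, shared_motifs=[0, 1, 2],
                                        private_motifs=([], []))
pair_private = synth.make_cell_type_pair(base, shared_motifs=[],
                                         private_motifs=([0, 1], [2]))

tables_shared = experiments.truth_kmer_tables(pair_shared, k=6)
tables_private = experiments.truth_kmer_tables(pair_private, k=6)

j_shared = kmers.top_fraction_jaccard(*tables_shared.values(), fraction=0.10)
j_private = kmers.top_fraction_jaccard(*tables_private.values(), fraction=0.10)
print(f"top-10% 6-mer Jaccard, cell types sharing all motifs:   {j_shared:.3f}")
print(f"top-10% 6-mer Jaccard, cell types with private motifs:  {j_private:.3f}")

t0 = tables_private["CT0"]
print("\nhighest-scoring 6-mers in CT0 (private motifs 0 and 1):")
ranks = kmers.rank_kmers(t0)
for km in ranks.index[ranks <= 5].tolist():
    row = t0.table.loc[km]
    print(f"  {km}  score={row['score']:.3f}  instances={int(row['count'])}")

delta = kmers.rank_delta(tables_private["CT0"], tables_private["CT1"])
moved = delta.reindex(delta["delta"].abs().sort_values(ascending=False).index)
print("\nlargest rank changes CT0 -> CT1 (positive = less important in CT0):")
print(moved.head(5)[["rank_a", "rank_b", "delta"]].to_string())

print("\nCell types sharing regulatory motifs have overlapping top k-mer "
      "sets (higher Jaccard); k-mers inside a cell type's private motifs "
      "swap ranks between the two tables.")
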