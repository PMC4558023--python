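"""Allele-selective polysome loading from simulated allele counts.

Simulates three samples in which 10% of genes carry a cis variant acting on
expression (same allelic imbalance in cytosol and polysomes) and 10% a
variant acting on polysome loading only (balanced cytosol, 4:1 polysomes),
then calls AEI and the cross-fraction difference statistic.
"""

from polyload import SimParams, simulate_dataset
from polyload.allelic import gene_aei_table, snp_ratio_table

params = SimParams(n_genes=300, depth_mean_rna=200, seed=42)
dataset = simulate_dataset(params)

snp = snp_ratio_table(dataset.allele_counts, min_reads=20)
aei = gene_aei_table(snp, aei_threshold=2.0, difference_threshold=2.0)
ok = aei[aei["status"] == "OK"]

print(f"gene x sample observations passing filters: {len(ok)}")
print(f"AEI (>=2-fold) in cytosol:   {ok['aei_cyt'].sum()}")
print(f"AEI (>=2-fold) on polysomes: {ok['aei_poly'].sum()}")
print(f"cytosol-vs-polysome difference >=2-fold: {ok['difference_flag'].sum()}")

truth = dataset.truth.genes.set_index("gene_id")
flagged = ok.loc[ok["difference_flag"], "gene_id"].unique()
hit = (truth.loc[flagged, "group"] == "loading_aei").mean()
print(f"fraction of difference-flagged genes that are true loading-AEI: {hit:.2f}")
# A high fraction means the D statistic isolates variants that act on
# polysome recruitment rather than on overall expression.
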