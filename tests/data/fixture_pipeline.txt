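annotation = "tss.bed"
gene_models = "genes.bed12"
reads = "reads.tsv"
spikeins = "spikeins.tsv"
cell_labels = "cells.tsv"
ref_filter_threshold = 0.2
promoter_distance_bp = 1000
min_tss_total = 100
min_pair_per_cell = 0.3
min_pair_per_cell_de = 0.5
rpk_cell_gate = 50
binomial_alpha = 0.05
bimodal_min_total = 5
bimodal_ratio = 2.0
usage_min_expressed_frac = 0.2
usage_min_delta = 0.3
de_min_mean = 0.5
de_fold_change = 2.0
de_alpha = 0.05
group_test = "t"
analysis_cell_type = "typeA"
compare_cell_types = ["typeA", "typeB"]
seed = 202
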