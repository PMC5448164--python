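n_genes = 20
n_cells = 50
cell_types = {"typeA": 0.5, "typeB": 0.5}
tss_per_gene = {"1": 0.35, "2": 0.55, "3": 0.1}
prob_promoter_pair = 0.1
proximal_distance = [50, 900]
promoter_distance = [1000, 4000]
mode_probs = {"shared": 0.85, "independent": 0.08, "exclusive": 0.02, "bimodal_ratio": 0.05}
burst_on_rate = 1.0
burst_off_rate = 1.0
transcription_rate = 40.0
degradation_rate = 1.0
exclusive_mixing = 0.5
bimodal_fractions = [0.9, 0.5]
bimodal_weight = 0.5
capture_efficiency = 0.2
cell_size_sigma = 0.4
scatter_sd = 10.0
background_rate = 0.5
tss_width = 60
gene_length = 10000
n_spikeins = 20
spikein_mean = 2.0
spikein_exact_frac = 0.75
umi_length = 6
duplication = {"2": 0.5, "3": 0.3, "4": 0.2}
collision_free_umis = false
n_usage_shift_genes = 1
usage_shift_delta = 0.4
seed = 202
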