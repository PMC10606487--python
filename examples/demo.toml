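# Seeded end-to-end demo: simulate a cohort with one marker fully linked
# to the blood-pressure QTL and one unlinked marker, select extreme
# discordant pairs, estimate IBD sharing and run the linkage tests.
#
#   edsp run --config examples/demo.toml

[run]
outdir = "demo_out"
stages = ["simulate", "select", "ibd", "linkage", "summary", "power"]

[simulate]
n_families = 800
seed = 7

# QTL explaining half the trait variance (strong locus, illustrative)
[simulate.model_fractions]
qtl_frac_sbp = 0.5
qtl_frac_dbp = 0.5
polygenic_frac = 0.2

[[simulate.markers]]
name = "QTLM"
chromosome = "17"
theta = 0.0
n_alleles = 8

[[simulate.markers]]
name = "FAR"
chromosome = "11"
theta = 0.5
n_alleles = 8

[linkage]
phenotypes = ["sbp", "dbp", "pp"]
lrt = true
lrt_n_perm = 1000
lrt_seed = 3

[power]
selection = "edsp"
alpha = 0.05
power = 0.8
n_sim = 50000
seed = 5
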