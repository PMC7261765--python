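# Desk-scale pipeline profile: runs in a couple of minutes on one core.
# For a full analysis raise mixture_bootstraps to 1000, mcmc_iterations
# to 100000, mcmc_burn_in to 10000 and cv_bootstraps to 10000.
input_table: cohort.csv
output_dir: runs/example
region_mode: combined
residualize: false
mixture_bootstraps: 50
mcmc_iterations: 5000
mcmc_burn_in: 500
greedy_restarts: 5
cross_validation: true
cv_bootstraps: 100
cv_restarts: 5
stage_cutoff: 1
seed: 0
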