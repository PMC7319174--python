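# Default simulation parameters. Every value can be overridden via a user
# config file or keyword overrides; see cicadasim.config.load_config.
n_patches: 11
cycle_lengths: [10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
scenario: random_ages       # newborn_start | random_ages | random_ages_with_delays |
                            # single_patch | twenty_patch_random | clonal
burn_in_years: 2000         # migration and mutation off, delays off
main_years: 50000
migration_prob: 0.25        # per surviving adult, per year; uniform target patch
                            # (includes the origin). Calibrated as the smallest
                            # rate at which hybridization is strong enough that
                            # synchronized subpopulations can invade each other
                            # while randomly phased ones remain stable.
mutation_prob: 1.0e-4       # per transmitted allele
fecundity: 4                # female offspring per female, deterministic
initial_fill: 0.9           # founders per patch as a fraction of N
clonal: false               # offspring copy the mother's genotype (no mating)

patch:
  N: 10000                  # feeding cells per patch (carrying capacity)

growth:
  # Log-normal annual increment exp(N(mu, sigma^2)); mu is set so the mean
  # increment exp(mu + sigma^2/2) = 0.15, i.e. the size threshold is reached
  # in ~7 years on average and virtually always within 10.
  mu: -1.9421199848858813
  sigma: 0.3
  size_threshold: 1.0

predation:
  # Calibrated so a lone small group (<= 1% of N) suffers >= 90% mortality
  # while a full resident emergence (~N) suffers <= 10%.
  p: 4.0
  a: 1.0
  h: 0.01
  ramp_years: 1000          # linear predator ramp during the first burn-in years

delay:
  p_delay: 0.0              # annual probability a population-wide delay starts
  d: 10                     # delay length in years
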