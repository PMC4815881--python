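# Clinical assumptions for the population-screening cascade (all rates as fractions).
population_size: 1000000
lifetime_risk: 0.005              # average lifetime TGCT risk
mortality_rate: 0.028             # TGCT mortality among cases
chemo_rate: 0.65                  # chemotherapy administration rate among cases
biopsy_sensitivity: 0.975         # testicular biopsy sensitivity for CIS
biopsy_complication_rate: 0.028   # surgical complication rate of biopsy
semen_sensitivity: 0.67           # semen CIS assay sensitivity
semen_specificity: 0.98           # semen CIS assay specificity
uptake: 1.0                       # genotyping uptake in the population
top_fraction: 0.01                # PRS stratum selected for follow-up
tail_rr: 9.2                      # average relative risk in the selected stratum
residual_risk_after_orchidectomy: 0.0
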