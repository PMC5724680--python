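"""Simulate a multi-design IPD survival network with known truth.

The default preset mimics a four-treatment oncology network: radiotherapy
(RT) as reference, chemoradiation (CTRT), neoadjuvant chemotherapy plus
radiotherapy (CT+RT) and plus surgery (CT+S), across 15 trials of four
designs with one evidence loop.
"""

from rpnma import default_cervical_like_spec, simulate_network

spec = default_cervical_like_spec(seed=1)
data, truth = simulate_network(spec)

print(f"patients: {len(data)}, trials: {len(data.trial_ids)}")
print("designs:")
for d in spec.network.designs:
    trials = [t for t in data.trial_ids
              if set(data.trial(t).df["treatment"]) == set(d.treatments)]
    print(f"  {' vs '.join(d.treatments):24s} {len(trials)} trial(s)")
print("true log hazard ratios vs RT:",
      {lab: round(float(b), 3) for lab, b in
       zip(spec.network.contrast_labels(), truth["beta"])})
print(data.df.head().to_string())
# Each row is one patient: trial, assigned arm, follow-up time (years here)
# and event indicator (1 = death observed, 0 = censored).
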