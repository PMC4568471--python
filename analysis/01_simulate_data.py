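"""Generate the synthetic study population and hormone-sampling data.

Writes ``results/data/individuals.csv`` (1,078 females born 1941-1999 with
calving histories, mortality and study-end censoring) and
``results/data/gcm.csv`` (37 females sampled monthly for a year, thinned to
~354 samples), using the generator defaults that emulate the study
population.  Run from the repository root:

    python analysis/01_simulate_data.py [seed]
"""

import sys

from stressborn import io
from stressborn.synthetic import (
    GCMSimConfig,
    SimConfig,
    simulate_gcm,
    simulate_population,
)

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
sim = SimConfig(seed=seed)
gcm_cfg = GCMSimConfig(seed=seed + 1, missing_frac=0.203)

pop = simulate_population(sim)
gcm = simulate_gcm(gcm_cfg)

meta = {"config_hash": io.config_hash([str(sim), str(gcm_cfg)]), "seed": seed}
io.write_individuals(pop, "results/data/individuals.csv", meta)
io.write_csv(gcm, "results/data/gcm.csv", meta)

n24 = (pop.last_seen_age >= 24).sum()
print(f"simulated {len(pop)} females; {pop.censored.mean():.0%} censored at study end")
print(f"{n24} females reach the senescent phase (age 24+)")
print(f"{len(gcm)} hormone samples from {gcm.female_id.nunique()} females")
print("wrote results/data/individuals.csv and results/data/gcm.csv")
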