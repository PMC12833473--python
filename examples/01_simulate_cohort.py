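"""Generate a claims-like synthetic cohort with a latent confounder.

A binary "frailty" variable U (prevalence 0.3) raises both the odds of
treatment and the hazard of the outcome, and is proxied by 30 of the 45
diagnosis/prescription/laboratory codes. The true treatment hazard ratio
is 1.0, so any departure of the crude estimate from 1 is confounding.
"""

from hdpslib import SimulationScenario, simulate

sim = simulate(SimulationScenario(n_patients=2000, seed=42))

print(f"patients: {len(sim.master)}")
print(f"exposure prevalence: {sim.master.data['exposure'].mean():.3f}")
print(f"outcome rate: {sim.master.data['outcome'].mean():.3f}")
print(f"latent confounder prevalence: {sim.u.mean():.3f}")
for label, dim in sim.dimensions.items():
    n_proxy = len(sim.proxy_codes[label])
    print(f"dimension '{label}': {len(dim)} records, "
          f"{dim.records['code'].nunique()} codes ({n_proxy} proxies of U)")
# The proxy codes are the only trace U leaves in the data: the HDPS
# pipeline must find and adjust for them.
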