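"""Re-derive the costing calibration constants from stage-cost anchors.

The shipped configuration carries three kinds of calibration constants
(see docs/methods.md): per-strategy first-line dose-intensity factors, a
second-line intensity, and the assistance-program paid fraction for
second-line sunitinib.  Each is the solution of a linear equation that
matches one published stage cost of the original analysis to this
engine's discounted occupancy.  This script recomputes them from scratch
so a user who edits prices, dosing or curves can refresh the constants.
"""

from mrcc_cea import DecisionModel, apply_hr, compute_trace, load_default_config
from mrcc_cea.cohort import discount_vector
from mrcc_cea.costing import cycle_drug_cost, sae_expected_cost

# published discounted stage-cost anchors (2011 USD)
PFS_COST = {
    "interferon": 6802.82,
    "bevacizumab_interferon": 157562.65,
    "sunitinib": 81728.07,
    "interleukin2": 4184.96,
    "interleukin2_interferon": 10464.30,
}
IFN_PS_COST = 25817.48
IFN_PS_COST_SPAP = 19297.00

config = load_default_config()
model = DecisionModel(config)
n = config.engine.horizon
d = discount_vector(n, config.engine.discount_rate)

traces = {
    s.name: compute_trace(
        apply_hr(model.reference_pfs, s.hr_pfs.mean),
        apply_hr(model.reference_os, s.hr_os.mean),
        n,
        config.engine.state_model,
    )
    for s in config.strategies
}

print("first-line dose-intensity factors (solve: anchor = SAE + fees+fu + DI*acq):")
for s in config.strategies:
    occd = traces[s.name].occ_pfs * d
    sae = sae_expected_cost(s.sae, config.prices)
    acq = fixed = 0.0
    for drug in s.first_line:
        sched = config.dosing[drug]
        for t in range(n):
            full = cycle_drug_cost(sched, config.prices, t)
            fee = cycle_drug_cost(sched, config.prices, t, dose_intensity=0.0)
            acq += occd[t] * (full - fee)
            fixed += occd[t] * fee
    fixed += occd.sum() * config.prices.price("followup")
    di = (PFS_COST[s.name] - sae - fixed) / acq
    print(f"  {s.name:26s} {di:.6f}  (shipped {s.dose_intensity})")

ps_cycles = float((traces["interferon"].occ_ps * d).sum())
psc = IFN_PS_COST / ps_cycles


def steady(drug, intensity=1.0):
    return cycle_drug_cost(config.dosing[drug], config.prices, 1, dose_intensity=intensity)


slope = const = 0.0
for drug, share in config.second_line.shares.items():
    drugs = ("interferon", "interleukin2") if drug == "cytokines" else (drug,)
    w = share / len(drugs)
    for dr in drugs:
        slope += w * (steady(dr) - steady(dr, 0.0))
        const += w * steady(dr, 0.0)
const += config.second_line.bsc_share * steady("morphine") + config.prices.price("followup")
intensity = (psc - const) / slope
print(f"\nsecond-line intensity: {intensity:.6f} "
      f"(shipped {config.engine.second_line_intensity})")

psc_spap = IFN_PS_COST_SPAP / ps_cycles
sun_component = config.second_line.shares["sunitinib"] * steady("sunitinib", intensity)
kappa = 1.0 - (psc - psc_spap) / sun_component
print(f"assistance-program paid fraction (second line): {kappa:.6f} "
      f"(shipped {config.engine.spap_second_line_paid_fraction}; "
      f"equivalent mean duration {3/kappa:.2f} cycles)")
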