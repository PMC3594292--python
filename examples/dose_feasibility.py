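"""Dose bookkeeping: skin-to-air conversion, silicon DQE, feasible dose.

Scales a measured air dose to what an efficiency-optimized bench would
need: a 70%-DQE detector instead of the actual one, and gratings on 100 um
instead of 500 um silicon wafer supports.
"""

from talbotct import (
    FeasibilityScenario,
    air_dose_from_skin,
    feasible_dose,
    silicon_dqe,
    wafer_transmission,
)

print("Entrance-skin dosimeter reading 9.66 Gy, conversion factor 1.4:")
print(f"  air dose = {air_dose_from_skin(9.66, 1.4, 'divide'):.2f} Gy")

dqe = silicon_dqe(thickness_um=450.0, energy_kev=23.0)
print(f"\n450 um silicon sensor at 23 keV: DQE = {dqe:.3f}")
print("  (fraction of photons depositing energy in the sensor layer)")

for t in (500.0, 100.0):
    print(f"wafer transmission, {t:.0f} um Si at 23 keV: "
          f"{wafer_transmission(t, 23.0):.3f}")

scenario = FeasibilityScenario(
    target_dqe=0.70,
    wafer_thickness_actual_um=500.0,
    wafer_thickness_feasible_um=100.0,
    n_gratings=3,
    energy_kev=23.0,
)
rec = feasible_dose(actual_dose_gy=6.9, actual_dqe=round(dqe, 2), scenario=scenario)
print(f"\nMeasured tube-scan air dose: {rec.actual_air_dose_gy:.1f} Gy")
print(f"Feasible dose with a 70%-DQE detector and thinned wafers: "
      f"{rec.feasible_air_dose_gy:.2f} Gy (+-{rec.uncertainty_fraction:.0%})")
print(
    "\nThe dose scales with the DQE ratio and with the transmission change"
    "\nof every wafer in the beam cubed (three gratings)."
)
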