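"""One-command virtual experiment: phantom -> scan -> maps -> CNR table.

Builds a seeded mouse-abdomen slice, simulates a noisy phase-stepping CT
scan with the tube-source interferometer, reconstructs attenuation (mu)
and phase (delta) maps, and reports the three-ROI contrast-to-noise
analysis of the solid tumor with propagated uncertainties.
"""

from talbotct import RunConfig, run_pipeline

cfg = RunConfig(
    size=192,
    pixel_size_um=30.0,
    scene="mouse_abdomen",
    n_projections=240,
    n_steps=4,
    flux=1.6e4,  # photons per pixel and step
    outdir="scratch/example_run",
    seed=42,
)
report = run_pipeline(cfg)

for contrast in ("attenuation", "phase"):
    block = report[contrast]
    print(
        f"{contrast:12s} CNR = {block['cnr']:6.2f} +- {block['cnr_sigma']:.2f}"
        f"   ({block['units']})"
    )
if report["gain"]:
    g = report["gain"]
    print(f"relative contrast gain = {g['gain']:.1f} +- {g['sigma']:.1f} "
          f"(rounded: {g['rounded_gain']})")
else:
    print("relative contrast gain undefined:", report["gain_note"])

print(
    "\nThe tumor's refractive-index step against soft tissue is several"
    "\ntimes its attenuation step, so the phase image separates the lesion"
    "\nat photon budgets where the attenuation image cannot."
    "\nAll intermediates were written to", cfg.outdir,
)
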