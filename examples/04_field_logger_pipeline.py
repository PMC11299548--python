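"""Field logger pipeline: diurnal storage dynamics with and without
temperature adjustment.

Simulates a dry-season-like deployment — constant true water content, a
5 degC diurnal temperature swing, the water-bucket artefact — and shows
that the apparent diurnal storage cycle is entirely artefactual: it
vanishes once the series is temperature-corrected.
"""

import stemwc as sw

registry = sw.default_registry()
series, truth = sw.generate_field_series(sw.FieldGenConfig(seed=51, n_days=6))
print(f"simulated {len(series)} logger rows (15-min cadence, 6 days), "
      "constant true WC, 5 degC diurnal swing")

processed = sw.process_series(
    series,
    registry.transform("teros12"),
    registry.calibrations["TTC"],
    registry.temperature_model("water-bucket"),
)
print("pipeline:", " -> ".join(processed.metadata["pipeline"]))

unadj = sw.diurnal_cycle(processed, "delta_stwc_unadjusted")
adj = sw.diurnal_cycle(processed, "delta_stwc")
print(f"\ndiurnal peak-to-trough, unadjusted: {unadj.peak_to_trough:.2f} kg m-3")
print(f"diurnal peak-to-trough, adjusted:   {adj.peak_to_trough:.2e} kg m-3")
print("The ~4.9 kg m-3 unadjusted cycle is the temperature artefact for a")
print("5 degC swing; the adjusted series is flat, matching the constant truth.")

labels = ["first-half" if t.day <= 3 else "second-half"
          for t in processed.data["timestamp"]]
summary = sw.seasonal_aggregate(processed, labels)
print("\nper-period summary (kg m-3 and degC):")
print(summary.round(3).to_string())
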