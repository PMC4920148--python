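"""Simulate and analyze a full reporter screen.

Generates a 1280-compound dual-readout screen (16 plates, duplicates at 20
and 2 uM) with 4 injected transcriptional activators and 18 inhibitors,
then runs the analysis: per-well normalization, per-plate Z'-factor QC, and
viability-gated hit calling. The printed Z' values gauge the separation
between control and vehicle wells (>= 0.5 is an excellent assay window);
the hit list is compared against the injected ground truth.
"""

from htsrepurpose import (
    call_hits,
    compute_well_metrics,
    paperlike_config,
    qc_screen,
    simulate_screen,
)

dataset, truth = simulate_screen(paperlike_config(), seed=1)
print(f"simulated {len(dataset.wells)} well records "
      f"({len(dataset.layouts)} plates x 96 wells x 2 conc x 2 reps)")

metrics = compute_well_metrics(dataset)
qc = qc_screen(metrics)
print(f"Z' (activator control vs vehicle): "
      f"{qc['zprime_positive'].mean():.2f} +/- {qc['zprime_positive'].std(ddof=1):.2f}")
print(f"Z' (inhibitor control vs vehicle): "
      f"{qc['zprime_negative'].mean():.2f} +/- {qc['zprime_negative'].std(ddof=1):.2f}")
print(f"plates passing QC (both Z' >= 0.5): {int(qc['pass'].sum())}/{len(qc)}")

hits = call_hits(dataset, metrics=metrics, qc=qc)
counts = hits.counts()
print(f"hits called: {counts['activator']} activators (E >= 240), "
      f"{counts['inhibitor']} inhibitors (E <= 40)")

called = set(hits.hits["compound_id"])
injected = set(truth.active_ids)
print(f"recovered {len(called & injected)}/{len(injected)} injected modulators, "
      f"{len(called - injected)} false positives")
missed = injected - called
if missed:
    plates = truth.compounds.set_index("compound_id").loc[sorted(missed), "plate_id"]
    print(f"missed (on QC-failed plates): {dict(plates)}")
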