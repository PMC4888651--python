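# spheroct

Label-free, longitudinal viability analysis of 3-D tumor spheroid cultures
from optical coherence tomography (OCT) volumes.

## The problem

Three-dimensional in-vitro tumor models — e.g. ovarian cancer (OVCAR5)
nodules of 400–700 μm diameter grown on basement-membrane matrix — are the
standard testbed for therapies against small avascular metastatic lesions.
The usual read-out, the fluorogenic Live/Dead assay, struggles there: probe
penetration is limited, the assay is terminal (one timepoint), and
lysosome-disrupting treatments corrupt the calcein "live" signal outright.
OCT images these cultures label-free, at micrometer resolution and
millimeter depth, repeatedly over days — if the volumes can be turned into
quantitative viability metrics.

`spheroct` implements that analysis chain end to end, plus a synthetic
phantom generator with exact ground truth so every stage is testable without
instrument data.

## The metrics

Raw spectral interferograms are reconstructed per A-scan (DC removal,
apodization, FFT, positive-frequency magnitude) and stacked into intensity
volumes I(z, x, y). Two complementary treatment-response indices are then
computed per well:

**Surface-area-to-volume disruption index.** Cell death breaks cell–cell
adhesion, so treated spheroids shed material and fragment. Per xz
cross-section, every segmented object contributes its perimeter P and
enclosed area A; with slice thickness Δy,

    SA:V = Σ P·Δy / Σ A·Δy        [1/μm]
    disruption index = (SA:V_sample / SA:V_control) − 1

so 0 means "as intact as the no-treatment control". The unsubtracted ratio
(control ≡ 1) is also reported.

**Apoptotic density.** Apoptotic cells package their contents into dense,
strongly scattering vesicles. Within each nodule, voxels brighter than
1.7 × the nodule's mean intensity (70% above average) are candidate
apoptotic material; a size filter and a distance-transform watershed yield
individual bodies, and

    apoptotic density = Σ V_body / V_spheroid   ∈ [0, 1]

Both metrics are normalized to no-treatment controls, benchmarked against
the Live/Dead ratio live/(live+dead), summarized with pooled-variance
t-tests and 1.5·IQR box statistics, and compared across treatment arms and
days to detect combination-therapy synergy.

## Worked example

```python
from spheroct import (PhantomSpec, generate_phantom, segment_nodules,
                      detect_apoptotic_bodies, global_sa_to_v,
                      apoptotic_density, disruption_index)

control_spec = PhantomSpec(grid_shape=(96, 96, 96), voxel_pitch_um=(2, 2, 2),
                           n_spheroids=1, radius_range_um=(40, 55), seed=7)
treated_spec = PhantomSpec(grid_shape=(96, 96, 96), voxel_pitch_um=(2, 2, 2),
                           n_spheroids=1, radius_range_um=(40, 55),
                           fragmentation=0.3, apoptotic_fraction=0.10, seed=7)

results = {}
for label, spec in [("control", control_spec), ("treated", treated_spec)]:
    volume, truth = generate_phantom(spec)
    nodules = segment_nodules(volume)
    features = detect_apoptotic_bodies(volume, nodules, factor=1.7)
    results[label] = (global_sa_to_v(nodules), apoptotic_density(features))
    print(f"{label}: SA:V = {results[label][0]:.4f} 1/um, "
          f"apoptotic density = {results[label][1]:.3f} "
          f"(truth {truth.true_apoptotic_fraction:.3f})")

index = disruption_index(results["treated"][0], results["control"][0])
print(f"disruption index (treated vs control) = {index:.2f}")
```

prints

```
control: SA:V = 0.0467 1/um, apoptotic density = 0.002 (truth 0.000)
treated: SA:V = 0.1422 1/um, apoptotic density = 0.082 (truth 0.100)
disruption index (treated vs control) = 2.05
```

The treated phantom had 30% of its nodule displaced into detached fragments
and 10% of its volume seeded with bright apoptotic bodies: its
surface-to-volume ratio triples (disruption index 2.05 vs 0 for the
control) and the recovered apoptotic density tracks the seeded fraction
under fully developed speckle.

The same chain is available from the shell:

```sh
spheroct simulate  --config phantom.json --out well0/
spheroct analyze   --config wells.json   --out metrics.csv
spheroct report    --metrics metrics.csv --out report/
```

Each run writes a provenance sidecar (config hash, seed, version) so
deterministic stages reproduce bit for bit.

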