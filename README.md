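# podoquant

Quantitative image analysis for podocyte biology. The package covers the
three imaging readouts used to characterize podocyte injury and foot-process
effacement, together with seeded synthetic phantoms that make every analysis
stage testable against known ground truth:

- **Glomerular immunofluorescence** (`podoquant.glomquant`) — segment
  glomeruli in kidney-section images from a marker channel (classical
  smoothing + Otsu + size/diameter filtering) and quantify per-ROI mean
  fluorescence of a target protein, aggregated per glomerulus and per
  subject.
- **Filtration-slit morphometry** (`podoquant.pemp`) — podocyte exact
  morphology from super-resolution images of slit-diaphragm proteins
  (MAGI2, nephrin): detect the slit mask, skeletonize it, measure total
  slit length and capillary area, and report the **filtration slit density
  (FSD, µm⁻¹)** — slit length per capillary area, which drops as foot
  processes efface. Includes a line-profile FWHM estimator for verifying
  the effective optical resolution.
- **Larval vasculature** (`podoquant.vasctrack`) — in a zebrafish
  proteinuria screen, segment the tail vasculature from the per-pixel
  temporal variation of a short brightfield movie (circulating
  erythrocytes are the only moving structures), then measure mean
  intravascular gc-eGFP fluorescence; plasma-protein loss shows up as a
  reduced ratio versus the reference group.
- **Statistics** (`podoquant.stats`) — normality-dispatched group
  comparisons (Welch's t / Mann–Whitney; Brown–Forsythe ANOVA with
  Dunnett's comparisons vs control / Kruskal–Wallis), Pearson correlation,
  and ΔΔCt relative quantification for qPCR.
- **Synthetic data** (`podoquant.synthdata`) — seeded generators for all
  three image types with exact ground truth (label masks, true slit length
  and area, true plasma levels), plus small bundled study-design tables.
- **I/O, configuration, CLI** (`podoquant.io`, `podoquant.cli`) — TIFF +
  JSON-sidecar image I/O, a strict validated run configuration, a composite
  simulate→segment→quantify→compare pipeline, and a `podoquant` command-line
  interface wrapping every stage.

## Worked example

Generate a filtration-slit phantom with 40 % effacement, measure FSD with
both markers, check marker interchangeability across effacement levels, and
run the motion-based vessel pipeline:

```python
import numpy as np
from podoquant import pemp, synthdata, vasctrack

# --- filtration-slit morphometry on a seeded phantom -----------------------
spec = synthdata.SlitPhantomSpec(effacement=0.4, channel_noise_sd=(10.0, 10.0), seed=7)
stack, truth = synthdata.gen_slit_phantom(spec)

true_fsd = truth.true_slit_length_um / truth.true_capillary_area_um2
print(f"true FSD     : {true_fsd:.3f} /um")
for marker in ("magi2", "nephrin"):
    m = pemp.compute_fsd(stack.channel(marker), stack.pixels_per_micron, marker=marker)
    print(f"{marker:8s} FSD : {m.fsd_per_um:.3f} /um "
          f"(slit length {m.total_slit_length_um:.1f} um over {m.capillary_area_um2:.0f} um^2)")

# --- marker interchangeability across a range of effacement levels ---------
images = []
for i, eff in enumerate(np.linspace(0.0, 0.8, 8)):
    s, _ = synthdata.gen_slit_phantom(
        synthdata.SlitPhantomSpec(effacement=float(eff),
                                  channel_noise_sd=(10.0, 10.0), seed=100 + i)
    )
    images.append(s)
conc = pemp.marker_concordance(images)
print(f"marker concordance: r = {conc.pearson_r:.4f} over {len(conc.pairs)} images")

# --- larval vasculature: motion segmentation + plasma fluorescence ---------
movie, egfp, gt = synthdata.gen_vessel_movie(synthdata.MoviePhantomSpec(seed=5))
mask = vasctrack.segment_vessels(vasctrack.compute_motion_map(movie))
t = np.asarray(gt.vessel_mask) > 0
iou = (t & mask).sum() / (t | mask).sum()
v = vasctrack.measure_vascular_fluorescence(egfp, mask)
print(f"vessel-mask IoU vs truth: {iou:.3f}; mean vascular eGFP: {v:.1f}")
```

Output:

```
true FSD     : 2.100 /um
magi2    FSD : 2.147 /um (slit length 289.9 um over 135 um^2)
nephrin  FSD : 2.137 /um (slit length 288.6 um over 135 um^2)
marker concordance: r = 0.9992 over 8 images
vessel-mask IoU vs truth: 0.872; mean vascular eGFP: 100.0
```

The measured FSD sits within 2.3 % of the true value, the two slit markers
agree almost perfectly across the effacement range, and the motion-derived
vessel mask recovers the exact plasma fluorescence level (100 by default).

### Command line

The same functionality is exposed as a CLI. The composite pipeline
simulates a four-group kidney-section cohort (control, MCD, primary FSGS,
secondary FSGS), segments and quantifies every subject, and compares the
groups against control:

```bash
$ podoquant run --seed 1 --out demo_run
{
 "MCD": 1.32461783734934,
 "Prim FSGS": 0.6081405539086839,
 "Sec FSGS": 0.9971185565039304,
 "control": 1.0
}
```

The simulated effects are 1.3× (MCD), 0.6× (primary FSGS) and 1.0×
(secondary FSGS); the recovered ratios land within a few percent despite
20 % measurement noise. `demo_run/` contains `per_glomerulus.csv`,
`per_subject.csv`, `summary.json` (including the Dunnett comparison
records) and `run.log` with the fully resolved parameter set.

Other subcommands: `podoquant simulate section|slits|movie`,
`podoquant glomquant`, `podoquant pemp`, `podoquant vasctrack`,
`podoquant stats`. All accept `--help`.

## Documentation

See [`docs/methods.md`](docs/methods.md) for the measurement models,
generator assumptions, parameter defaults with units, and numerical
choices.
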