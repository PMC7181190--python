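# nervect

Segmentation, tracking and protocol scoring for microCT volumes of
contrast-stained peripheral nerves.

Iodine (Lugol's) staining makes the soft tissues of a peripheral nerve —
fascicles, interfascicular epineurium, adipocytes — separable in
laboratory X-ray microCT at micrometre voxel sizes, which in turn makes
it possible to trace individual fascicles along centimetres of nerve.
`nervect` implements the computational side of that workflow for
anatomists and neural-interface researchers:

* **Protocol scoring.** Grey-value line profiles across the tissues, and
  two scalar image-quality metrics used to choose staining time and scan
  settings: the *distinguishability score*

  $$d = |\bar i_f - \bar i_e| + |\bar i_e - \bar i_a| + |\bar i_a - \bar i_f|$$

  (the sum of pairwise absolute differences of the mean greys of
  fascicle, epineurium and adipocyte tissue, equal to twice the range of
  the three means), and the fascicle-to-background signal-to-noise ratio
  $\mathrm{SNR} = \mu_{fascicle} / \sigma_{background}$. The condition
  with the maximal score wins.

* **Volume conditioning.** End-slice trimming (cone-beam artefacts),
  percentile histogram stretching, a 3×3×3 median filter, a 1×1×5 moving
  average along the nerve axis, and two-sided grey-range binarization,
  with a multi-Otsu-based range suggestion.

* **Segmentation and tracking.** Seeded neighbourhood-connected region
  growing, morphological closing, slice-to-slice linking of fascicle
  cross-sections with explicit branch and plexus events, the
  boundary-loss rule (more than half of a footprint discontinues) and
  boundary-gain rule (two fascicles merged with no plexus within 3 mm),
  and the acceptability verdict (≥ N full-length fascicles, no confirmed
  loss or gain).

* **Validation.** Region areas, equivalent-circle diameters
  ($2\sqrt{A/\pi}$), percentage diameter differences against a reference,
  and Dice overlap against ground truth.

* **Synthetic nerve phantoms.** A generator of stained-nerve microCT
  volumes with five tissue classes at configurable grey levels, wobbling
  fascicle tubes with branch/plexus events, movement artefacts, and full
  per-voxel ground truth — so every stage above is testable end to end
  without scan data.

## Worked example

Generate a four-fascicle phantom (one branch, one plexus, 4 μm voxels,
mild noise), score its contrast and run the full chain:

```python
import nervect as nv
from nervect.phantom import example_nerve_spec, build_phantom, TissueClass

res = build_phantom(example_nerve_spec(rng_seed=7, noise_sd=0.02))
stats = nv.tissue_grey_stats(res.volume, res.tissue_labels)
print("per-tissue means:", {TissueClass(k).name: round(v, 3)
                            for k, v in stats.means.items()})
print("distinguishability d =", round(nv.distinguishability(stats).d, 3))

out = nv.run_pipeline(res.volume, nv.seeds_from_truth(res),
                      nv.PipelineConfig(min_fascicles=4), annotation=res)
print("acceptable:", out.report.acceptable,
      "| full-length tracks:", out.report.n_tracked,
      "| loss:", out.report.n_loss, "| gain:", out.report.n_gain)
seen = set()
for t in out.tracks:
    for e in t.events:
        if e.kind.value in ("BRANCH", "PLEXUS") and (e.kind, e.z_um) not in seen:
            seen.add((e.kind, e.z_um))
            print("event:", e.kind.value, "at z =", e.z_um, "um, partners", e.partners)
print("per-fascicle Dice:", {k: round(v, 3)
                             for k, v in nv.per_fascicle_dice(out, res).items()})
```

prints

```
per-tissue means: {'SPONGE_AIR': 0.18, 'CLINGFILM': 0.3, 'EPINEURIUM': 0.75,
                   'FASCICLE': 0.55, 'ADIPOCYTE': 0.919}
distinguishability d = 0.739
acceptable: True | full-length tracks: 4 | loss: 0 | gain: 0
event: PLEXUS at z = 228.0 um, partners (2, 3)
event: BRANCH at z = 516.0 um, partners (6, 7)
per-fascicle Dice: {1: 0.931, 2: 0.931, 3: 0.967, 4: 0.999, 5: 0.965, 6: 0.961}
```

The measured tissue means match the phantom's configured greys, `d` is
twice their range, the tracing is acceptable (all four founding
fascicles span the volume; the plexus between tubes 2 and 3 and the
branch of tube 4's lineage are recognised as anatomy, not as boundary
gain), and every fascicle is recovered with Dice ≥ 0.93.

The same stages are available from the shell:

```sh
nervect phantom --config spec.yaml --out phantom/ --seed 7
nervect segment --stack phantom/volume.tiff --seeds seeds.json \
        --range 0.45,0.65 --out mask.tiff
nervect track --mask mask.tiff --min-fascicles 4 --report report.json
nervect validate --seg mask.tiff --ref phantom/instance_labels.tiff \
        --z 120 --out diameters.csv
```

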