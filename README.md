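# iscocta

Inter-frame speckle contrast OCT angiography (OCTA) processing in Python:
from repeat-frame OCT volumes (or raw spectral interferograms) to en-face
angiograms and a vessel area density (VAD) statistic, with a synthetic
speckle phantom so the whole chain can be exercised and verified without
instrument data.

OCTA maps perfusion without contrast agents by exploiting speckle dynamics:
when N consecutive B-scan frames are captured at each slow-axis location,
static tissue speckle is nearly identical across the repeats while speckle
inside vessels renews frame to frame. Per location the package computes

- the mean image `I_s(x,z) = (1/N) Σ_i I(x, y_i, z)`,
- the inter-frame speckle contrast
  `K_s(x,z) = (1/(N−1)) Σ_{i=1}^{N−1} |I_{i+1} − I_i| / (I_{i+1} + I_i)`,
  a per-pixel statistic in [0, 1] that is ~0 in static tissue and large
  where speckle decorrelates (flow), and
- the flow image `I_flow = I_s · K_s`, the mean image masked by the
  contrast image so static structure is suppressed.

The flow volume is then projected en face over a depth range, gray levels
are normalised, the angiogram is smoothed morphologically, binarised
(Otsu by default; 1 = vessel, 0 = noise) and cleaned, and
`VAD = vessel pixels / total pixels` is reported together with the final
masked angiogram.

Intended users: groups doing small-animal or preclinical OCTA who need a
transparent, testable reference implementation of speckle-contrast flow
processing and VAD quantification.

## Worked example

```python
import iscocta

# a seeded synthetic acquisition: 64 locations x 4 repeats x 64 x 64,
# three tubes of radius 2/3/4 voxels, 80% speckle renewal per frame, SNR ~ 10
volume, truth = iscocta.reference_phantom()

mean_vol, contrast_vol, flow_vol = iscocta.process_volume(volume)
result = iscocta.quantify(flow_vol, iscocta.QuantConfig(),
                          protocol=volume.protocol)

print(f"in-vessel K_s  {contrast_vol[truth.vessel_voxels].mean():.3f}")
print(f"static   K_s  {contrast_vol[~truth.vessel_voxels].mean():.3f}")
print(f"recovered VAD {result.vad:.4f}  (truth {truth.enface_vessel_fraction:.4f})")
print(f"Dice overlap  {iscocta.dice_coefficient(result.mask.pixels, truth.enface_mask):.3f}")
```

prints

```
in-vessel K_s  0.489
static   K_s  0.166
recovered VAD 0.2437  (truth 0.2979)
Dice overlap  0.900
```

Speckle inside the decorrelating vessels carries roughly three times the
inter-frame contrast of static tissue, the recovered vessel map overlaps
the ground truth at Dice 0.90, and the measured vessel area density is
within ~18% of the true en-face vessel fraction (automatic thresholding
slightly under-segments dim vessel edges).

The same pipeline is available from the shell:

```sh
iscocta simulate --out sim/                 # phantom volume + ground truth
iscocta angiogram sim/volume.tiff --out ang/
iscocta quantify ang/flow.tiff --out quant/
iscocta run --out results/ --seed 5         # everything end to end
```

`quantify` writes `mask.png`, `masked_flow.tiff` and a plain-text `report.txt`
embedding the VAD and the full resolved configuration.

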