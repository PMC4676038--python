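# shgvernier

Forward simulation of second-harmonic-generation (SHG) and two-photon
excited fluorescence (TPEF) image formation in striated muscle, built to
study **illusory "SHG vernier" patterns**: Y-shaped or bridging SHG signal
that appears *between* adjacent myofibers whose sarcomere registers are
staggered, even though no myosin crosses the cell boundary.

## Who this is for

Microscopists and image analysts who use label-free SHG of muscle (e.g. in
zebrafish embryos, or as a readout of sarcomere integrity in disease
models) and need to know which features of an SHG image are structure and
which are coherent-imaging artifacts. The package simulates both contrast
mechanisms from the same geometry so their signatures can be compared
pixel for pixel.

## The model

Illumination is a scalar paraxial Gaussian beam with waist
`w0 = λ/(π·NA_obj)` and Rayleigh range `zR = π n w0²/λ`:

```
E(ρ, z) = (w0/w(z)) · exp(−ρ²/w(z)²) · exp(i[k n z − ψ(z) + k n ρ²/(2R(z))])
```

where `ψ(z) = arctan(z/zR)` is the **Gouy phase**, which slips by π as the
focus is traversed.

Muscle is a set of point scatterers: rectangular blocks of myosin thick
filament with a *signed* effective susceptibility χ — positive on one side
of each sarcomere's M-line, negative on the other (bipolar filament
polarity) — plus fluorophore density on a chosen sarcomeric target.

The two signals differ only in how emitters combine:

* **SHG (coherent).** Far-field amplitude per emission direction ŝ:
  `A(ŝ) = Σₙ χₙ E(rₙ)² exp(−i k₂ ŝ·(rₙ − focus))`, with `k₂ = 2kn`.
  Detected intensity integrates `|A|²` over the condenser collection cone
  (NA 0.55). The squared drive field carries *twice* the Gouy phase:
  emitters before and after the focus acquire opposite phase offsets
  `∓2ψ`, so two fibers at different depths whose χ patterns are offset by
  half a period (geometric cancellation) can still interfere
  *constructively* when the focus sits between them — the vernier
  illusion.
* **TPEF (incoherent).** `I = Σₙ fₙ |E(rₙ)|⁴`. No phases, no
  cross-emitter interference: stagger cannot create signal where no
  fluorophore exists.

A raster renderer scans the focus over 2D sections or 3D volumes, and a
reconstruction pipeline ("M-line pipeline") builds a synthetic SHG volume
from nothing but segmented M-line positions — one antiparallel filament
pair per M-line along the locally estimated fiber axis — so that any
inter-fiber signal in the output is provably artifactual.

## Worked example

Two parallel fibers (sarcomere period 1.9 µm, half-filament 0.8 µm),
staggered by half a period versus perfectly aligned, imaged at
λ = 0.850 µm with NA 0.8/0.55:

```python
import numpy as np
from shgvernier import (
    CollectionCone, ImageGrid, build_staggered_pair, derive_beam,
    interfiber_enhancement, line_profile, render,
)
from shgvernier.tissue import DEFAULT_SEPARATION_AXIS

beam = derive_beam(wavelength_um=0.850, na_objective=0.8, na_condenser=0.55)
cone = CollectionCone(na=0.55)
print(f"waist w0 = {beam.waist_um:.4f} um, Rayleigh range zR = {beam.rayleigh_range_um:.4f} um")

sep = np.asarray(DEFAULT_SEPARATION_AXIS)
grid = ImageGrid(
    origin_um=-0.5 * 33 * 0.1 * sep,
    axes=np.stack([[1.0, 0.0, 0.0], sep]),
    shape=(76, 33), pixel_size_um=0.1, section_kind="longitudinal",
)
images = {
    stagger: render(build_staggered_pair(stagger_phase=stagger, spacing_um=0.12),
                    grid, beam, cone)
    for stagger in (0.5, 0.0)
}
midline = ([0.1, 0, 0], [7.5, 0, 0])
shg = interfiber_enhancement(images[0.5], images[0.0], *midline, "shg")
tpef = interfiber_enhancement(images[0.5], images[0.0], *midline, "tpef")
frac = line_profile(images[0.5], *midline, 256, "tpef").values.max() / images[0.5].tpef.max()
print(f"inter-fiber SHG enhancement (staggered/aligned) = {shg:.2f}")
print(f"inter-fiber TPEF enhancement                    = {tpef:.2f}")
print(f"TPEF midline / in-fiber band peak               = {frac:.3f}")
```

prints

```
waist w0 = 0.3382 um, Rayleigh range zR = 0.5623 um
inter-fiber SHG enhancement (staggered/aligned) = 2.08
inter-fiber TPEF enhancement                    = 0.92
TPEF midline / in-fiber band peak               = 0.086
```

Reading: staggering the fibers roughly **doubles** the SHG signal on the
myosin-free midline between them (the illusory vernier), while TPEF is
indifferent to stagger (ratio ≈ 1) and leaves the midline dark (≈ 9 % of
the in-fiber band peak) — the fluorescence image reports the true
geometry, the SHG image does not.

## Command line

```sh
shgvernier simulate   --out pair.tif --stagger 0.5 --noise-seed 1   # render + Poisson noise
shgvernier reconstruct --mlines mlines.csv --out synthetic_shg.tif  # M-line pipeline
shgvernier analyze    --image pair.tif --channel shg \
                      --profile "0.2,0,0:7.0,0,0" --period 1.9      # band metrics
```

## Layout

| module | contents |
| --- | --- |
| `shgvernier.beam` | Gaussian focal field, Gouy phase, beam parameter derivation |
| `shgvernier.coherent` | far-field SHG sum, condenser-cone quadrature, TPEF |
| `shgvernier.tissue` | sarcomere/myofiber builders, staggered pair, M-line fixtures |
| `shgvernier.imaging` | raster renderer, grids, Poisson noise, TIFF + JSON sidecar I/O |
| `shgvernier.mlines` | point/mask ingestion, axis estimation, synthetic-SHG reconstruction |
| `shgvernier.profiles` | line profiles, bands per period, M-line contrast, enhancement ratios |
| `shgvernier.config` / `shgvernier.cli` | YAML config and the `shgvernier` command |

See `docs/methods.md` for model assumptions, parameter defaults and known
limitations.
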