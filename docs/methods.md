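# Methods

## Optical model

Illumination is a **scalar paraxial Gaussian beam**. The complex focal
field at cylindrical coordinates (ρ, z) about the propagation axis is

    E(ρ, z) = (w0/w(z)) · exp(−ρ²/w(z)²)
              · exp(i [k n z − ψ(z) + k n ρ² z/(2(z² + zR²))]),

with waist `w0 = λ/(π NA_obj)` (1/e² convention, a single named function so
alternative conventions can be swapped), `w(z) = w0 √(1+(z/zR)²)`,
Rayleigh range `zR = π n w0²/λ`, and Gouy phase `ψ(z) = arctan(z/zR)`.
The curvature term is written with `1/R(z) = z/(z²+zR²)`, finite at the
focal plane. The amplitude is normalized to 1 at the focus; all lengths
are micrometres.

A scalar paraxial field at NA 0.8 is an idealization — a vectorial
(Debye–Wolf) focus has somewhat tighter axial confinement and weaker
tails. The field evaluator sits behind a single function
(`beam.focal_field`) so a high-NA model can replace it without touching
the signal or rendering code.

**SHG** is coherent. Each scatterer contributes a far-field amplitude per
emission direction ŝ

    A(ŝ) = Σₙ χₙ E(rₙ; focus)² exp(−i k₂ ŝ·(rₙ − focus)),   k₂ = 2 k n,

i.e. the drive is the *squared* fundamental field (twice the Gouy phase)
and the medium is dispersionless (`n(ω) = n(2ω)`, no phase mismatch Δk).
Detected intensity integrates `|A(ŝ)|²` over the forward condenser cone
(transmitted-light detection only; no epi-SHG). χ is a signed scalar:
polarization and the full susceptibility tensor are out of scope, the
sign encodes thick-filament polarity. The dipole radiation-pattern
obliquity factor is omitted; over the narrow forward cone (half-angle
24.4° at NA 0.55 in water) it is nearly constant and would rescale, not
reshape, the collected signal.

**TPEF** is incoherent: `I = Σₙ fₙ |E(rₙ)|⁴`, with emission collection
efficiency absorbed into the (arbitrary) intensity units.

## Collection-cone quadrature

Gauss–Legendre in cos θ × uniform midpoint in φ, defaults
`n_theta = 16, n_phi = 32`. Weights sum to the cone solid angle exactly;
a single scatterer at the focus therefore integrates to
`2π(1 − cos θ_max)`, which doubles as a sanity check in the tests. The
test suite holds the production quadrature to within 1 % of a naive
direct double loop at 4× resolution.

## Tissue geometry

A sarcomere contributes two rectangular myosin blocks, one per half
thick filament, meeting at the M-line with opposite χ sign. Blocks are
discretized on a regular lattice (default spacing λ/10 = 0.085 µm,
chosen over Monte-Carlo point clouds for reproducibility); equal counts
on the two sides make the per-sarcomere χ sum exactly zero. Defaults,
all configurable:

| parameter | default | note |
| --- | --- | --- |
| wavelength λ | 0.850 µm | standard two-photon/SHG excitation for muscle |
| NA objective / condenser | 0.8 / 0.55 | typical high-resolution scanning values |
| refractive index n | 1.33 | aqueous tissue |
| sarcomere period | 1.9 µm | embryonic zebrafish scale (model default) |
| half-filament length | 0.8 µm | midpoint of the physiological 0.6–1 µm range; the constructors refuse values outside that range unless explicitly overridden |
| block transverse halfwidth | 0.35 µm | myofibril bundle scale |
| fiber center separation | 2.3 µm | two-fiber scenario (gap parameter 1.6 µm) |
| fiber-stacking direction | tilted 30° from the optical axis | see below |
| lattice spacing | 0.085 µm | ≥ 4 samples per half filament enforced |

### Why the oblique two-fiber geometry

The vernier mechanism needs the two fibers at *different axial depths*
relative to the focus: the squared drive field gives them Gouy offsets
`e∓2iψ`, and near `ψ ≈ π/4` (depth offset ≈ zR ≈ 0.56 µm) a half-period
stagger flips destructive into constructive interference. But TPEF can
only resolve the two fibers if they are also separated *transverse* to
the beam, because the axial extent of `|E|⁴` (≈ 1.4 µm FWHM here) smears
any purely axial gap of a micrometre or two. Adjacent myofibers in a real
embryo are stacked in whatever direction the mounting dictates, so the
package's default scenario tilts the stacking direction 30° away from the
optical axis: the axial component (≈ 1.0 µm) drives the Gouy interference
and the transverse component (≈ 0.6 µm) lets TPEF separate the fibers.
This also reproduces the characteristic *diagonal* placement of vernier
bridges between staggered fibers.

The two requirements pull against each other, and the scalar-Gaussian
axial tails set the compromise: at the defaults the acceptance run
measures a staggered/aligned midline SHG ratio ≈ 2.1 with a TPEF midline
at ≈ 9 % of the in-fiber band peak. Pulling the fibers further apart
drives the TPEF midline toward zero but weakens the Gouy enhancement
(both fall off once the fiber depth offset exceeds ~2 zR); bringing them
closer does the opposite. The defaults favor the SHG effect, which is the
phenomenon under study, while keeping the TPEF channel qualitatively dark
between fibers.

Similarly, the rendered M-line minimum in a single-fiber SHG profile is
≈ 35 % of the adjacent band peak rather than zero: the on-axis far field
cancels exactly by antisymmetry (the two-point oracle in the tests
verifies < 10⁻³), but the x-odd residual radiates into off-axis
directions that the NA-0.55 cone still collects. This residual is a
converged property of the cone-integrated scalar model (stable under 2×
lattice and quadrature refinement), not a discretization artifact.

## Rendering

Pixel values are point samples of the signal at pixel centers
(scanned-focus convention; voxel-center coordinates, 0-based). The
renderer exploits the factorization of the far-field phase: the
propagation factors `exp(−i k₂ ŝ·rₙ)` are focus-independent, so the
amplitudes for all pixels reduce to one complex matrix product per
scatterer block, chunked to bound memory. The result is algebraically
identical to per-pixel evaluation (a regression test enforces agreement
to 1e-9) and pixels are order-independent by construction. A configurable
budget on pixel × scatterer products raises an explicit cost error with a
suggested coarsening instead of silently thrashing.

Poisson background noise is a separate, seeded, optional stage
(`Poisson(signal_scale·v + background_rate)` per pixel); raw renders stay
noise-free so invariants can be tested on them.

## M-line reconstruction pipeline

Inputs are either CSV/JSON point lists or binary 3D masks (one M-line per
26-connected component, centroid in voxel-center µm coordinates). Local
fiber axes are estimated per point as the principal direction of the
displacement vectors to its k nearest neighbors (default k = 4), signs
oriented along the cloud's global principal direction; isolated points
fall back to the global axis with a warning. Each M-line then seeds one
straight antiparallel filament pair (no intra-sarcomere curvature), with
per-point lengths either fixed or drawn uniformly from 0.6–1 µm with a
seed. The per-fiber scatterer sets are verifiably disjoint in space, so
any inter-fiber signal in the rendered volume is an imaging artifact —
the pipeline's purpose. Automatic TPEF segmentation is deliberately not
attempted; the package consumes segmentation output.

## Profile analysis

Band counting uses peak prominence ≥ 0.1 × the profile maximum
(configurable); plateaus count once at their leftmost sample. Period
windows are anchored an eighth of a period before the first detected
maximum so a band falling exactly on a window edge is not split between
windows. M-line contrast is the mean of (value at M-line)/(max within
± half period). The inter-fiber enhancement ratio compares the midline
maximum of a staggered render against an aligned control on the same
grid. All analysis functions are pure.

## Synthetic data: what it does and does not emulate

The fixture generator produces regular M-line lattices with optional
Gaussian jitter (mimicking manual-segmentation imprecision) and
alternating stagger phases. It does **not** emulate fiber curvature,
sarcomere length dispersion along a fiber, χ magnitude disorder,
depth-dependent aberration or scattering, detector dark counts, or the
low signal-to-noise of deep-tissue TPEF. Passing tests therefore
demonstrate the *optical* origin of inter-fiber SHG under clean geometry;
they do not certify quantitative agreement with any particular tissue
volume, and the reconstruction pipeline is intended for qualitative
comparison.

## Numerical notes and degenerate inputs

- Empty scatterer sets render to zero (not an error); empty masks warn.
- `R(z)` is evaluated as `z/(z²+zR²)`; no special-casing at z = 0.
- Intensities use `|A|² = Re² + Im²` to avoid complex temporaries.
- The global χ sign is arbitrary: flipping every sign leaves all
  intensities unchanged (tested).
- Coordinates round-trip through CSV bit-exactly (`%.17g` +
  round-trip float parsing).
- Seeds: every stochastic stage (jitter, per-filament lengths, noise)
  takes an explicit integer seed; nothing draws from global state.

## Known limitations

Scalar paraxial focus at NA 0.8; forward-only SHG collection; no
dispersion, no polarization tensor, no pulse structure; straight
filaments; uniform χ within a filament (no axial taper). Problem sizes in
the test and acceptance runs (4 sarcomeres per fiber, 0.05–0.1 µm pixels,
0.085–0.12 µm lattice spacing) were chosen as the smallest configurations
whose headline ratios are converged to a few percent.
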