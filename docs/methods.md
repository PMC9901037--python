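# Methods

This note documents the models, conventions and numerical choices behind
`mhcgroove`, and what its synthetic test bed does and does not establish.

## Structure model and unmodeled-region detection

A structure is a flat atom table in **author residue numbering** (the
literature on these complexes names residues Ile52, Tyr59, Asn63, Cys76,
Trp167 in author numbering, so nothing is renumbered) plus a per-chain full
polymer sequence taken from the sequence record (SEQRES/entity) when
present. Alternate locations are collapsed to the highest-occupancy
conformer, ties broken by altloc identifier order. A residue with any
modeled atom counts as modeled: the analyses target whole-residue
crystallographic disorder, not side-chain-only disorder.

Unmodeled regions are maximal runs of residues absent from the coordinate
record, found from numbering gaps between consecutive modeled residues and
from sequence-record residues never modeled. The sequence record is aligned
to author numbering starting at a configurable `seq_start` (default 1,
correct for the MHC heavy chain). This is a pure coordinate-absence
criterion; it approximates, but cannot reproduce, a density-level (1σ)
visibility judgement, which would need the maps.

Peptide **P positions** are anchored on the engineered disulfide: the
peptide Cys whose Sγ lies within 2.5 Å (a standard disulfide cutoff) of
heavy-chain Cys76 Sγ is P7; P1 is six positions N-terminal along the chain;
residues before P1 are extensions P-1, P-2, … If no partner is found the
mapping fails loudly and must be given manually.

## Superposition and Cα shifts

Rigid superposition is least-squares (Kabsch), implemented via
`scipy.spatial.transform.Rotation.align_vectors` with the residual
recomputed directly (the library's reported residual loses precision near
zero). Degenerate (collinear or < 3 point) problems are rejected. The
default fit frame for structure pairs is the heavy-chain α1α2 domain Cα
set, residues 1–180, restricted to residues modeled in **both** structures
— the conventional peptide-MHC reference frame — and is configurable. No
outlier trimming is applied. Shifts are reported to 0.01 Å. When the two
structures number their peptides differently (20mer vs 8mer), the target
residue can be named separately per structure so P1 pairs with P1.

## Contacts

Hydrogen bonds use a donor/acceptor dictionary over the 20 standard
residues (backbone N donor except proline; backbone O/OXT acceptor; the
usual side-chain sets). Criteria default to donor–acceptor ≤ 3.5 Å with a
donor–H–acceptor angle ≥ 120° applied only when hydrogens exist — crystal
structures carry none, so there distance alone decides. Hydrophobic
contacts are carbon–carbon pairs ≤ 4.5 Å, reported once per residue pair at
the minimum distance. Both cutoffs are field-standard defaults and
configurable; output is canonicalised so selector order does not matter,
and tightening any cutoff yields a subset of the looser result.

## Trajectories and RMSF

A trajectory is frames × atoms × 3 in Å with strictly increasing times and
a per-atom (chain, residue, name) topology. The required on-disk dialect is
multi-model PDB (one MODEL per frame, identical atom records); binary
formats load through mdtraj when available. PDB carries no timestamps, so
times are synthesised on a uniform grid with spacing `dt_ps` (default
20 ps, a typical MD sampling interval — set it to match the trajectory).

Global motion is removed by per-frame Kabsch superposition on a fit
selection (default: all heavy-chain Cα). The default reference is the
two-pass mean structure: superpose on frame 0, recompute the mean once,
re-superpose — more stable than a first-frame reference for short
trajectories. RMSF is per-atom root-mean-square deviation from the
time-average position, reported per residue as the mean over selected atoms
(Cα only by default; all-heavy-atom available).

One caveat the test suite makes explicit: when the fit selection itself
fluctuates, the six rigid-body degrees of freedom absorb a small share of
the variance, biasing RMSF low by roughly `sqrt(1 − 6/3N)` for N fitted
atoms. Tests that check the closed form σ√3 therefore fit on a static
subset or use enough residues that the bias is below tolerance.

## Interaction geometry

The P1↔partner definitions follow the residue types:

| P1  | partner | distance definition                              |
|-----|---------|--------------------------------------------------|
| Phe | Tyr59   | ring center – ring center (+ normal–normal angle)|
| Ala | Tyr59   | P1 Cβ – Tyr59 ring center                        |
| Phe | Ile52   | P1 ring center – Ile52 Cδ                        |
| Ala | Ile52   | P1 Cβ – Ile52 Cδ                                 |

Other P1 types are rejected explicitly. Ring centers are unweighted means
of the six-membered ring atoms (≥ 5 required); ring normals are best-fit
plane normals (SVD) with the sign fixed by the right-hand rule over the
ordered ring atom sequence, so orientation angles are reproducible.
Rings deviating more than 0.5 Å from planarity are flagged.

Orientation angles are reported **unfolded** in [0°, 180°]: the reported
ensemble peaks (≈90° for the 8mer complexes, ≈110°/150° for the 20mers)
live on that scale, and folding would alias 150° onto 30°. Folding to the
stacking deviation s = min(θ, 180° − θ) ∈ [0°, 90°] happens only inside
π-π classification: the peak of the s distribution ≥ 60° is T-shaped,
≤ 30° parallel-like, otherwise intermediate, with a half-bin tolerance at
the thresholds because a histogram locates a peak only to half a bin. The
published FV-20mer-like geometry (150°, s = 30°) sits exactly on the
parallel-like boundary, which is why that tolerance matters.

The CH-π criterion is distance ≤ 6.0 Å (P1 ring center to Ile52 Cδ) **and**
C–H–X angle ≥ 120° (Cδ, its bonded hydrogen, ring center X). The cutoffs
are literature-standard values chosen so that the reported interacting
geometries (≈5 Å, 120–150°) pass and the ≈10 Å non-interacting ensembles
fail; both are configurable. MD frames use the explicit Cδ hydrogen
pointing closest to the ring; on hydrogen-free crystal structures three
ideal tetrahedral methyl hydrogens (1.09 Å, 109.47° from the Cγ–Cδ axis)
are constructed and the one nearest the ring center used.

Probability distributions are density-normalised histograms — bin width
0.25 Å for distances, 5° for angles, no kernel smoothing — with the peak at
the center of the maximal bin (ties to the lowest value) and FWHM from
linear interpolation around the peak's contiguous above-half-maximum
region.

## Amino-group rotation (ω)

ω is the torsion over Cys76:CA, P7:CA, P1:CA, P1:N in the IUPAC sign
convention, range (−180°, 180°]. Negative values (−110°/−73° in the
long-peptide crystal states) mean the terminal amino group points up out of
the A pocket; positive values (+96°/+98° in the native controls) mean it
points down.

Time series are unwrapped by adjusting each step by a multiple of 360° so
consecutive changes stay below 180°; the output is congruent to the input
modulo 360° at every sample. A step of exactly 180° is ambiguous and
resolved toward no adjustment (logged). Smoothing is a centered sliding
average over ±window/2 (default 10 ns) with truncated windows at the edges
rather than dropped samples; smoothing wrapped angles is refused because
averaging across the ±180° seam corrupts values — unwrap first.

Rotation events: after the smoothed series has dwelt in the start band
(default −100° ± 45°) for at least 1 ns — a dwell requirement that rejects
single-frame noise — an event is recorded when it comes within tolerance of
the end value (default +100° ± 45°) **modulo 360°**, so an unwrapped trace
ending near −260° counts. The detector re-arms after a fresh dwell,
allowing multiple events. Bands match the observed up (≈ −110°/−73°) and
down (≈ +96°/+98°) states and are configurable.

## Melting temperature

Replicate curves are averaged pointwise, smoothed by a centered moving
average (default 11 points, sized for grids near 0.06–0.1 °C/point), and
differentiated by central differences; the derivative is smoothed with the
same window before the extremum search, which keeps the location unbiased
for a symmetric transition while suppressing grid-scale noise. Tm is the
temperature of the derivative **minimum** (matching a descending
fluorescence transition; a maximum option covers dye conventions with
ascending signal). The extremum is refined by parabolic interpolation: a
least-squares parabola over the contiguous region deeper than half the
extremal depth — symmetric about the true inflection for a logistic-like
transition, hence unbiased and far more noise-robust than a three-point
parabola on a peak that is ~3.5× the transition width wide. Extrema on the
grid boundary and flat derivatives are errors; all interior local extrema
are also listed for multi-transition curves.

## Synthetic data: what it emulates, what it does not

Each generator is a pure function of its parameters and seed, uses its own
independent random stream, and returns its ground truth alongside the data:

- **Harmonic trajectories**: rigid poly-alanine Cα scaffold with i.i.d.
  isotropic Gaussian displacement per residue (σ per coordinate), so
  expected RMSF is exactly σ√3. Defaults for the flexibility tests mirror
  the reported contrast: σ = 0.5 Å in the flexible window (residues 41–62)
  against 0.1 Å elsewhere, a 5× contrast.
- **Ring pairs**: two ideal aromatic hexagons at a programmed center
  distance and normal–normal angle with optional per-atom jitter; test
  geometries use the reported bands (5–6–7–10 Å; 90°/110°/150°).
- **Rotation traces**: piecewise-sigmoidal paths through waypoint
  schedules, wrapped and noise-corrupted (σ up to 20°, comparable to the
  thermal scatter of the real traces).
- **Gapped structures**: poly-alanine helices whose sequence record covers
  residues the coordinates omit.
- **Melt curves**: descending logistics on a 25–95 °C, 0.1 °C grid with
  noise as a fraction of amplitude.
- **Groove-complex stand-ins**: minimal synthetic peptide–MHC complexes
  with a real Cys76–P7 disulfide geometry, a P1 ring, engineered disorder
  ranges, an exactly programmed ω (the P1 amide nitrogen is placed by
  torsion geometry), and optional P1/P2 Cα offsets for shift measurements.

These fixtures emulate the *statistical structure* the analyses consume —
stationary Gaussian fluctuations, programmed transitions, engineered
disorder — not force-field physics, real protein folds, anisotropic or
correlated motion, or density-based disorder. Passing tests therefore
demonstrate that the measurements recover known ground truth through the
full file-based pipeline, including the published value patterns the
stand-ins are engineered to; they do not certify agreement with deposited
experimental coordinates, which requires running the same code on the real
files.

## Problem sizes

The test suite and acceptance script use 2000-frame fluctuation ensembles,
2000-frame ring ensembles, 100–1000 seeded series for the unwrap and
event-count properties, 180-residue scaffolds, and 701-point melt curves —
sizes at which the closed-form expectations hold to the stated tolerances
while the whole suite runs in well under a minute.

## Known limitations

- Missing-density detection is coordinate-based; electron density is never
  consulted.
- Only Phe and Ala P1 residues are supported in the interaction analysis
  (Trp and others would need their own distance definitions).
- The hydrogen-bond angle test silently degrades to distance-only on
  hydrogen-free structures.
- Sequence-record alignment assumes a contiguous author numbering starting
  at `seq_start`; insertion codes are not interpreted.
- `dt_ps` must be supplied correctly for time-windowed operations
  (smoothing, dwell) when trajectories carry no timestamps.
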