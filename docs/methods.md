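# Methods

This note documents the models, estimators and numerical choices behind the
`neuropil` package: how astrocytic coverage is quantified on triangulated
neuropil reconstructions, how astrocytic processes are sorted into leaflets
and branchlets, how complexity–entropy spectra of process images are
computed, and how the glutamate spillover simulator works. It also states
what the synthetic-data generator does and does not emulate, so the meaning
of a passing test suite is clear.

## Geometry engine

All mesh stages share one exact point-to-surface query structure
(`neuropil._geometry.SurfaceDistance`). Candidate triangles are pruned with
a k-d tree over triangle centroids: the k-nearest centroids give an upper
bound on the distance, and every triangle whose centroid ball could beat
that bound is then evaluated with the exact point–triangle routine
(Ericson's region decomposition), so results equal a brute-force scan.
Signed distance uses angle-weighted pseudonormals (face, edge and vertex
normals chosen by the closest simplex feature), which is robust on closed,
consistently oriented meshes; inside/outside tests are its sign. A few
outlier-sized triangles (long slivers in imported meshes) are checked
exhaustively so they cannot inflate the pruning radius. Load-time cleaning
merges duplicate vertices within 1e-6 μm, drops degenerate faces and
unreferenced vertices, and re-orients closed meshes to positive signed
volume. Units are μm throughout; scene manifests declare the unit of their
mesh files and the loader rescales.

## Equidistant surfaces and volume-fraction profiles

The astrocyte volume fraction (VF) around a reference structure is defined
per spherical-shell bin of width Δd = 30 nm out to 0.99 μm: the fraction of
the shell's volume occupied by astrocytic processes, where the shell at bin
k is the region between the equidistant surfaces at distances kΔd and
(k+1)Δd from the reference.

*Equidistant surfaces* are built by shrinking an enclosing triangulated
sphere: each vertex moves along the line to its closest point on the
reference until its distance equals d. A single rearrangement is exact for
convex references; the projection is iterated (up to 50 times) until the
audited vertex-distance error falls below Δd/3 = 10 nm, which also handles
concave references such as dumbbells and spine necks. Surfaces that leave
the scene block or may self-intersect are flagged, not repaired.

*VF estimation* is by seeded uniform Monte-Carlo sampling rather than exact
mesh booleans: points drawn in the reference's bounding box (inflated by
d_max) are binned by their distance to the reference and classified against
every astrocytic mesh. VF per bin is the astrocytic point fraction with a
binomial standard error; bins with an empty denominator are reported as
missing, never as zero. This is robust to imperfect meshes and its error is
quantifiable (standard errors ≤ 0.01 at the default 2×10⁵ samples on the
synthetic suite).

Four reference modes mirror the coverage questions: distance from the PSD
centre of mass (full concentric spheres), from the PSD edge (its boundary
polyline), from the lateral spine surface, and from the full membrane of a
bouton or dendritic-shaft chunk. For the spine-surface mode, shell parts in
the presynaptic half-space (least-squares PSD plane offset to the PSD's
outer face, bouton side) and the dendritic half-space (plane normal to the
neck axis at the spine base, shaft side) are excluded from numerator and
denominator alike. Dendritic shafts are split into 1-μm chunks along their
principal axis (a remainder under 0.5 μm merges into the last chunk), the
planar cut faces are recorded, and sample points nearest to a cut face are
excluded so only the membrane-covered lateral surface acts as reference.

Spine heads are separated from necks at the minimal-cross-section locus
along the base→PSD axis; the head's equivalent-sphere radius classifies the
spine (mushroom at ≥ 0.2 μm, thin below; threshold inclusive). Headless
stubs fall back to the whole-spine equivalent radius with a warning. Bouton
radii are equivalent-sphere radii from volume. Astrocyte–spine contact is
scored on minimal surface-to-surface distance (direct contact at ≤ 50 nm),
with the full percentage-versus-distance curve also reported.

## Leaflet / branchlet sorting

Local surface-to-volume ratio (SVR) separates thin astrocytic sheets
(leaflets) from organelle-bearing tubes (branchlets). A secant sphere of
radius 0.3 μm (the alternative reported radius of 0.6 μm is a parameter) is
centred at points sampled area-uniformly over the astrocyte surface at 50
points/μm²; the astrocytic membrane area and volume inside each sphere are
counted from two global seeded point clouds of known density (surface
samples; uniform interior samples accepted by the inside test), queried
through a k-d tree. In the thin-plate limit SVR → 2/t and in the thin-rod
limit SVR → 2/ρ; both are recovered within 10 % in their regimes of
validity (structure much thinner than the secant sphere).

The (area, volume) pairs are standardised and split by 2-means (10
restarts, seeded); the cluster with higher mean SVR is the leaflet class.
Faces take the majority class of the samples within one secant radius.
Whole leaflets are connected components of leaflet-class faces; components
whose area falls below the secant resolution (default 0.05 μm²) are painted
back to branchlet. Components in mutual surface contact are merged so
composite meshes whose parts abut without shared vertices behave like
stitched ones. Each leaflet is parented to the branchlet component it
touches most; leaflets touching no branchlet are flagged orphans. Leaflet
volume comes from capping the open attachment boundary (centroid fans) and
applying the divergence theorem. Nearest-neighbour distances between
leaflets on a shared parent use attachment centroids projected onto the
parent surface; note that the majority vote blurs attachment zones by up to
the secant radius, and sheets spaced closer than the secant diameter can
merge — an intrinsic resolution limit of the method, visible in the tests.
The nearest-neighbour distance distribution is fitted with a k-component
1-D Gaussian mixture by EM (seeded, 5 restarts), with a degeneracy flag for
collapsed components.

## Complexity–entropy spectra

Binary segmentation stacks are sum-projected along Z (mean projection is a
parameter; the two differ only by a constant and give identical H and C)
and 2× block-mean downsampled. Each image is decomposed into local
scale–orientation features by a Fourier-domain tight frame: Meyer-type
radial windows partition log-frequency into a lowpass plus 4 dyadic scales,
and raised-cosine angular windows partition orientation (modulo π) into 4,
8, 8 and 16 sectors per scale; the squared filters sum to one everywhere,
so band powers partition signal energy exactly (any backend satisfying this
band-partition contract can be plugged in). Coefficients are kept complex
so the unpaired Nyquist bins lose no energy.

The normalised band powers at a pixel form a probability vector P over
N = 36 features (the lowpass is excluded by default: it encodes mean
intensity, not oriented structure, and would compress entropy toward zero).
Relative entropy is H = S[P]/log₂N with S the Shannon entropy in bits;
complexity is C = H·J/J_max where J is the Jensen–Shannon divergence of P
from the equiprobable distribution and J_max its value at a singular
distribution. Pixels whose total feature power is below 1e-12 of the image
mean are masked; rendered maps write zeros there. The implementation agrees
with a literal scalar-loop evaluation of these formulas to 1e-12.

The spectrum of a class is summarised against the pooled median complexity
in 51 entropy bins, smoothed with a cubic smoothing spline (scipy's
standard smoothing heuristic; the bandwidths of the excess-complexity
kernel density estimates follow Silverman's rule). Excess complexity is a
pixel's C minus the curve at its H.

A stripe-corruption toy validates the measures: swapping random neighbour
pixels of a regular stripe image (f swaps per pixel, cumulatively) raises
the mean entropy monotonically while the mean complexity passes through a
transient interior maximum (near f ≈ 4 at the defaults) before relaxing
toward the fully shuffled limit.

## Glutamate spillover simulator

A synapse of radius r (0.05–0.45 μm) sits at the centre of a cubic 10-μm³
world: two hemispheric terminals of radius r separated by a 20-nm cleft.
The PSD occupies the central disc of radius r/3, which reproduces the
17–150-nm PSD range over the swept radii; the perisynaptic/extrasynaptic
membrane annulus spans from the PSD edge to the cleft edge, and a 50-nm
transporter-free collar surrounds the terminals. 2,000 glutamate molecules
are released instantaneously from the cleft centre and take Gaussian steps
(variance 2DΔt per axis, Δt = 1 μs, 10⁴ steps) with D* = 0.33 μm²/ms in the
cleft and D*/λ² (λ = 1.45) outside. Steps into a terminal are rejected
(molecule stays put); the world boundary is absorbing and the escape
fraction is reported — at 10 ms roughly half the molecules have left the
10-μm³ world, as expected for free diffusion over ~1 μm.

Glial glutamate transporters at 20 μM populate the space beyond the collar,
tracked as free-transporter pools per 10-nm concentric shell (shell free
volumes estimated once per geometry by fixed-seed Monte Carlo). A free
molecule in a shell binds with probability 1 − exp(−k_on·[T_free]·Δt);
bound molecules either unbind in place or are translocated (removed from
the extracellular pool), after which the transporter immediately returns to
its shell pool. The simplified 3-state GLT1 cycle, the 7-state AMPA
("GluA") scheme and the 5-state NMDA ("GluN") scheme are shipped as JSON
configuration (rates from the classic kinetic literature, recorded at room
temperature); every rate is Q10 = 3 corrected to 36.5 °C, matching the
temperature treatment of the model as a whole. A load-time check enforces
the schemes' defining relation: GluN unbinds glutamate more slowly and has
the higher steady-state affinity.

Two volume-averaged concentration waveforms drive the receptor pools by
master-equation integration (exact matrix exponentials per waveform sample,
cached on a 1 % logarithmic concentration grid; occupancy is verified to
remain a probability vector to 1e-9, and constant-drive steady states match
the rate-matrix null space to 1e-8): the cleft volume above the PSD for the
synaptic pools, and the cleft annulus between the PSD edge and the cleft
edge for the extrasynaptic pools — extrasynaptic receptors sit on the
postsynaptic membrane outside the PSD, so they sample the cleft
concentration over that annulus rather than the open space beyond the
synapse. This reading is what makes the simulator reproduce the headline
behaviour: at the smallest synapses the annulus exposure is too brief for
AMPA-receptor activation, at large synapses the prolonged millimolar
exposure desensitises receptors during the concentration rise, and the peak
extrasynaptic GluA open probability therefore passes through an interior
maximum at r = 0.15 μm — the crossover where the annulus concentration
falls through the receptor's saturation point α/k₁ ≈ 0.9 mM. Alternative
readings in which the extrasynaptic volume lies beyond the cleft edge (an
open annulus or a 50-nm shell over the terminal surfaces) make both the
peak and the time-integral of extrasynaptic glutamate decrease
monotonically with r, so no receptor scheme that responds non-decreasingly
to concentration and duration can produce the interior maximum there; this
was verified numerically before the annulus reading was adopted. One known
residual: under this reading the extrasynaptic GluN peak open probability
rises mildly with r (slow-unbinding integrator kinetics benefit from the
longer exposure) rather than falling.

The synaptically activated transporter current (STC) is the
transporter-binding flux; its latency is the time to 10 % of the (0.1-ms
boxcar-smoothed) peak and its centroid is ⟨t⟩ = Σt·I(t)/ΣI(t). Repeats of
a release are simulated as one batch of independent molecules with
per-repeat transporter pools and averaged (statistically identical to
sequential repeats). The full nine-radius sweep with five repeats runs in
about a minute on one CPU.

## Synthetic neuropil generator

The generator stands in for tissue reconstructions that are not publicly
available, at a desk-scale 3×3×3-μm block. Spines are closed surfaces of
revolution (sphere head on cylinder neck, exact union volume in closed
form) carrying open spherical-cap PSDs opposite the neck; head radii default
to the uniform 0.05–0.4 μm range of hippocampal spines. Boutons are
spheres, shafts are subdivided cylinders. Astrocytic material comes as
partial spherical shells ("wraps") at an exact offset, thickness and
solid-angle coverage around a target — the true VF profile is then known in
closed form — and as branchlet tubes with attached leaflet sheets at
controlled spacings and azimuths, with per-face class labels and
attachment-distance truth tables. Profile polylines are resampled so no
triangle is much longer than the azimuthal spacing (long slivers degrade
every surface-sampling stage). Placement uses capsule-aware rejection
sampling so neuronal objects never interpenetrate; head radii that cannot
be packed into the remaining free space are redrawn, as in a densely packed
block. All randomness derives from a single scene seed; equal seeds give
byte-identical scenes. Rasterisation to binary stacks evaluates analytic
primitives where available (spheres, shells, cylinders, boxes) and the mesh
inside test otherwise.

What the generator does not emulate: Reconstruct-style mesh noise and
alignment artefacts, organelle content (leaflet/branchlet truth is assigned
by construction, not by ER/mitochondria detection), realistic packing
statistics of neuropil, curvature-realistic spine morphologies beyond
sphere+cylinder unions, and the population composition of any real tissue
block. Passing tests therefore demonstrate that the estimators recover
known ground truth under controlled geometry — not that real-tissue
population numbers would be reproduced.

## Problem sizes used by the test suite

The suite scales simulations to what the estimators need rather than to
tissue scale: VF profiles use 6×10⁴–1.2×10⁵ Monte-Carlo points per object
(standard errors of a few percent per bin), classification scenes use one
tube with five sheets at the default densities, mixture fits use 400–500
distances, and the spillover sweep runs the full protocol (9 radii × 5
repeats × 2,000 molecules × 10⁴ steps). The whole suite runs in a few
minutes on one CPU.

## Known limitations

- The equidistant-surface mesh is used for visualisation and auditing; VF
  shells are defined by distance binning, which is equivalent up to the
  audit tolerance but never produces self-intersection artefacts.
- Leaflet segmentation resolution is set by the secant radius: attachment
  positions blur by up to that radius and sheets closer than the secant
  diameter can merge.
- Step rejection at membranes slightly under-represents near-wall mobility
  relative to specular reflection; at Δt = 1 μs the per-step displacement
  (~30 nm outside the cleft) keeps the bias well below the Monte-Carlo
  noise.
- Transporters recycle instantly on translocation; the STC time course is
  the binding flux, not a full transporter-current model.
- The extrasynaptic GluN trend with synapse radius is the one qualitative
  behaviour of the source analysis the simulator does not reproduce (see
  the spillover section).
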