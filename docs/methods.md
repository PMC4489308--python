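# Methods

## Model

`solvaxs` computes the net solution-scattering intensity of a solute
from two explicit-solvent coordinate ensembles: the solute system (A)
and a matched pure-water system (B). The electron density of each
system is split by a closed envelope into inside and outside parts;
because the outside densities of the two systems are statistically
identical bulk water, only the inside densities contribute to the net
intensity, which is what makes the calculation possible on a finite
simulation box. The net intensity at fixed solute orientation is

    D(q) = ⟨|Ã|²⟩ − ⟨|B̃|²⟩ + 2 Re[ −⟨B̃⟩* ⟨Ã − B̃⟩ ],

with Ã, B̃ the envelope-restricted amplitudes Σ_j f_j(q) e^(−i q·r_j)
and ⟨·⟩ the frame average of each system taken separately (unequal
frame counts are allowed). The three terms are the scattering of the
solute plus hydration layer, the excluded solvent, and the correlation
between bulk water and the density contrast inside the envelope.
I(q) = ⟨D⟩_Ω averages over solute orientations. The assumptions are
those of the underlying decomposition: the same envelope is applied to
both systems and to all frames, frames are approximately uncorrelated,
and the water box is large enough that the envelope fits inside it
(checked, and an error otherwise).

Amplitudes are accumulated per (q-shell × frame) in a streamed loop, so
memory stays O(J_q) per shell regardless of frame count; per frame the
atom sum is grouped by chemical species so the form factor is evaluated
once per species, not per atom.

## Envelope

The envelope is built from an icosphere (a regular icosahedron whose
triangles are recursively subdivided and re-projected onto the unit
sphere; depth 4 → 2562 vertices, the default). Each vertex direction u
gets the radius

    r(u) = max over atoms a with ρ_a < d of [ t_a + sqrt(d² − ρ_a²) ],

the exit point of the ray from the union of atom-centered spheres of
radius d (t_a, ρ_a the along-ray and perpendicular coordinates of atom
a relative to the envelope center). This guarantees every vertex is at
least d from every solute atom of every build frame; between vertices
the planar triangle surface may dip marginally below d, which is
accepted. The center is the mean solute coordinate over all build
frames — a centroid maximizes star-shapedness for globular solutes.
Rays that pass farther than d from every atom (deeply concave
directions) receive a small positive floor radius (10⁻³ Å).

Point containment intersects the point's direction with the planar
triangle mesh (a nearest-face search plus exact cone tests), so the
inside test is exact ray–mesh containment; ties on the surface resolve
to inside. Selection is atom-wise: a water molecule may be split by the
boundary, because the decomposition partitions *density*, not
molecules.

The diameter D entering the quadrature rule J_q = max{100, 0.2 (qD)²}
is the envelope diameter rather than the bare solute diameter: the
scattering volume is the envelope, and the larger D only increases the
number of quadrature points, never decreases accuracy.

## Form factors

Cromer–Mann coefficients (four Gaussians plus constant, neutral atoms)
are bundled as a plain-text data file transcribed from the
International Tables; the q=0 value reproduces the electron count to
tabulation precision (±0.05 e, verified in tests). Ion charge is
ignored unless an ionic entry is configured explicitly; exotic ions
always scatter with their own element's form factor.

Water oxygen and hydrogen are separate species (OW/HW) with two
corrections acting on disjoint parameter slots, so they commute
exactly (asserted in tests):

* **Electron-withdrawing correction** (Sorenson-style): a
  multiplicative factor 1 + α e^(−q²/2δ²) with δ = 2.2 Å⁻¹ and α fixed
  by a charge transfer of 0.4238 e per hydrogen, the partial charge of
  the parameterisation's water model. The corrected entries are
  rescaled by Z/f(0) (a ~10⁻⁴ adjustment absorbing the tabulation
  residual) so one corrected water molecule counts exactly 10 electrons
  at q = 0.
* **Solvent-density correction**: the bulk electron density of the
  pure-water system is measured (nominal electrons over frame-averaged
  box volume) and Δ = (ρ_target − ρ_sim)·V/N_water electrons are added
  to a q-independent constant on the water-oxygen entry — a uniform
  per-molecule charge at the oxygen site. The default target is
  334 e nm⁻³ (pure water). The correction applies identically wherever
  the table is used (both systems) and is never fitted to experiment.
  Placing the charge on the oxygen site alone is the simplest scheme;
  spreading it over all three sites would alter intensities only
  beyond q ≈ 2π/1 Å and is not implemented.

## Orientational average

Per |q| shell, J_q unit directions are generated by the deterministic
golden-angle (generalized Fibonacci) spiral — reproducible, with
nearest-neighbor spacing within a factor two of the ideal √(4π/J). The
J_q rule's floor of 100 points governs the small-q region; the
0.2 (qD)² branch keeps the quadrature error roughly uniform in q.
Against the exact Debye sum for a rigid 20-atom configuration the
relative error stays below 0.5% over q ∈ [0, 1] Å⁻¹ (asserted in
tests).

## Statistical errors

`sigma_stat` is a delete-one-block jackknife: frames of each system are
split into up to 10 contiguous blocks, I(q) is recomputed per
leave-one-block-out replicate from the stored per-block amplitude sums,
and the jackknife standard error is reported. This is plumbing — a
sanity scale for fitting, not a rigorous error model for correlated MD
frames.

## Buffer subtraction

The three-term intensity realises the total scheme
I_sam − I_buf. The reduced scheme I_sam − (1−v) I_buf adds back
v · I_buf with I_buf taken as the orientation-averaged
excluded-solvent term ⟨|B̃|²⟩, scaled by V_solute/V_envelope when the
solute volume is supplied. This is an explicit approximation to the
exact reduced-scheme correction (which requires a separate treatment of
the solvent structure factor) and is flagged in the output metadata.
v is taken from the user, or estimated as V_solute/V_envelope.

## Fitting

The experimental curve is transformed (I_fit = f·I_exp + c), the
computed curve is not. The error-weighted metric
χ² = N⁻¹ Σ [(I_calc − f I_exp − c)/σ_exp]² has a closed-form minimizer
(2×2 weighted normal equations). The log-space metric
χ²_log = N⁻¹ Σ [log I_calc − log(f I_exp + c)]² is minimized by a
deterministic two-stage search: a coarse logarithmic grid over f with a
bounded one-dimensional search for c, then Nelder–Mead polish, with the
feasibility constraint f·I_exp + c > 0. When σ_exp is absent the
weighted metric is not faked with unit weights; the log metric is used
and a warning issued. The calculated curve is linearly interpolated
onto the experimental grid; points outside the computed range are
dropped, never extrapolated. Both metric values and their square roots
are reported.

## Guinier analysis

ln I is fitted linearly in q² on a window iterated to self-consistency
from the lowest 20% of points, admitting points with q·R_g ≤ 1.3 (the
community-standard bound). Note an inherent property of this window:
for a uniform solid sphere the exact form factor decays faster than the
Gaussian over the upper part of the window, so the fitted R_g
overshoots the true value by ≈1.7% systematically; recoveries of the
analytic √(3/5)·R therefore sit near, but inside, a 2% tolerance.
A positive constant background biases R_g downward (asserted as a
direction in tests). A non-decaying low-q curve is rejected as
non-physical rather than returning an imaginary R_g.

## Unit conventions

Internally all coordinates are Å and scattering vectors Å⁻¹ in the
q = 4π sin(θ)/λ convention; nm⁻¹ and the s = 2 sin(θ)/λ convention
(q = 2πs) are converted at the I/O boundary only.

## Structure preparation

Hetero molecules are classified against the polymer chains: blacklist
residue names (GOL, BNG, BOG, PG, PE, PGE) are removed unconditionally
and first — this must override the size rule, or long PEG chains would
be kept; otherwise a molecule is kept if it is covalently attached
(heavy-atom distance < 1.9 Å, or < 2.4 Å when one partner is
S/Se/metal, following standard covalent radii; CONECT records also
count), forms > 2.5 contacts per heavy atom within 3.5 Å, has > 20
heavy atoms, or is named HEM. Classification is per-molecule and
order-independent. The blacklist names PG/PE collide with phospholipid
residue names in some entries; the printed list is followed regardless.
Selenomethionine repair renames MSE→MET and Se→SD sulfur with
coordinates untouched. No missing atoms are added and no sterics are
fixed — that is the job of a simulation engine, out of scope here.

## Synthetic systems

The generator emulates the statistical structure the method assumes,
not physical water: rigid 3-site waters (O–H 0.9572 Å, H–O–H 104.52°)
placed by dart-throwing with a minimum O–O distance of 2.4 Å and
uniform random orientations; solute models (single atom, uniform
sphere cluster, helix) with optional per-frame Gaussian jitter; waters
excluded from a 2.8 Å-radius union of solute-atom spheres, with the
water count reduced accordingly so the far-field density matches the
companion pure-water box. Frames are independent draws. Defaults: a
20-atom cluster of 4–5 Å radius in a 30–40 Å box at 334 e nm⁻³, 4–10
frames — sizes chosen so a full three-term curve on a laptop core takes
seconds. What passing tests on these systems show: correctness of the
amplitude/averaging/subtraction algebra, the envelope geometry and the
correction plumbing. What they do not show: agreement with real
hydration-layer structure, which has density excess and orientational
ordering the generator deliberately does not model (tests needing
density contrast impose it explicitly).

Run-length configuration rules are provided as calculators: the frame
count N_fr = 2·10⁵/N_A^0.77 (N_A the solute atom count; quick = ¼,
thorough = 5×) and the equilibration discard max(5% of total time,
3 ps), capped at the total and applied as a preprocessing drop of early
frames, toggleable.

## Numerical choices and limitations

* Envelope containment tolerance 10⁻⁹ (relative) at the surface; ties
  resolve inside.
* Quadrature and jackknife are fully deterministic; the only random
  number use is in the synthetic generator, always seeded.
* The Debye oracle is O(N²) and guarded at 2000 atoms.
* No resolution smearing, polydispersity, SANS variant, anomalous
  scattering, mmCIF output, or ensemble reweighting.
* The reduced-scheme buffer term is the approximation described above,
  not the exact correction.
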