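# Methods

## Distance engine

The inter-surface distance is defined as the directed per-vertex
nearest-point distance: for every articular vertex of the talar dome, the
Euclidean distance to the nearest point anywhere on the tibial plafond
surface (nearest point on a triangle, not nearest vertex). This is the
simplest transparent contract consistent with "relative distance between
articular surfaces"; clinical packages do not publish their exact
definition, so the choice is this package's own and is stated here so
results are interpretable. Consequences of the choice: the map is
asymmetric (talus→tibia), sampling resolution is the dome mesh's vertex
density (no resampling), and distances are exact with respect to the target
triangulation.

Implementation: Ericson's closest-point-on-triangle region method,
vectorized over point–triangle pairs, with a KD-tree on triangle centroids
used only to prune candidates. Pruning preserves exactness: after an upper
bound `ub` is obtained from the k = 8 nearest centroids' triangles, every
triangle whose nearest point could still beat `ub` must have its centroid
within `ub + r_max` of the query (`r_max` = the largest centroid-to-corner
radius), and all such triangles are evaluated exactly. The test suite
checks the engine against an exhaustive per-triangle brute force written
with a different formulation (plane foot + clamped edges, scalar loops) to
1e-9 mm.

## Projection and orientation

The axial view is the plane normal to a caller-supplied axis (default the
world z-axis, matching the scanner frame in which the synthetic joints are
generated), with +y along a caller-supplied anterior direction (default
world +y) and +x completing a right-handed frame. Whether the grid should
be aligned to the scanner or to an anatomical talar axis is genuinely open;
exposing the axis as an input rather than guessing keeps the method
well-defined for either choice. Left feet are mirrored at projection time
(x → −x) so that +x is always anatomically lateral and a single right-foot
convention serves all downstream scoring; mesh-free grid tables for left
feet are correspondingly expected in image-frame column order and mirrored
back on input, which makes anatomically identical patterns score
identically on both sides.

## Grid scoring

The bounding rectangle of the non-excluded projected samples is always
split into 4×4 *equal* squares; the anatomical centre (midpoint of the
medio-lateral and antero-posterior extents) only anchors the axes that
decide each square's quadrant label, with a square belonging to the
quadrant that contains its own centre. Square centres are expressed in
normalized units (rectangle mapped to [−0.5, +0.5]²), giving centres at
±0.125 and ±0.375; this makes TWS dimensionless and invariant to foot
size, so values are comparable across patients.

Scoring rules and their edge cases:

- Sample→square assignment uses half-open intervals, closed on the last
  row/column, so every sample lands in exactly one square.
- Cyst samples contribute distance 0 to their square's mean and are counted
  in `cyst_fraction`; a fully cystic square therefore scores DMC exactly 1
  (the defined maximum) and a partially cystic square is interpolated
  continuously.
- DMC = 1 − mean distance may be negative when the mean gap exceeds 1 mm;
  that is the formula's intended extension, not an error.
- Empty squares carry no DMC and contribute 0 to both sums, but the divisor
  stays 16 (the total number of squares is fixed by the construction).
- Classification uses strict sign rules with an exact-zero neutral class.
  Because an exact zero is measure-zero in floating point, TWS is rounded
  to 3 decimals before classification by default (configurable, including
  no rounding and an explicit `zero_tol` band); this reproduces the
  clinical behaviour in which a patient can be exactly neutral at the
  recorded precision, and implies an effective neutral band of
  |TWS| < 5·10⁻⁴.

For a noiseless linear field d = d0 + gx·cx + gy·cy the score has the
closed form TWS = (−Σcx²/16)·(gx, gy) = (−0.078125·gx, −0.078125·gy),
since Σcx = Σcy = Σcx·cy = 0 and Σcx² = Σcy² = 1.25 over the 16 centres.
This identity is the package's primary analytic oracle.

## Reliability statistics

ICC(2,1) — two-way random effects, absolute agreement, single measure — is
computed from the two-way ANOVA mean squares,

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

with the F-based McGraw–Wong 95% interval. Perfect-agreement tables
(MSE = MSC = 0) return estimate 1 with a degenerate interval [1, 1]; a
table with zero total variance has no defined ICC and raises. The
interpretation bands are printed in the literature with shared endpoints
(0.5–0.75, 0.75–0.9, 0.9–1); they are implemented half-open with the
boundary belonging to the higher band, which is deterministic and
order-preserving. ICC is computed separately for TWSx and TWSy (plus a
pooled mean as a convenience); pooling conventions differ between studies,
so both views are exposed rather than one guessed.

Group comparisons are gated per group by Shapiro–Wilk at α = 0.05: both
groups normal → independent-samples t test with mean ± SD summaries,
otherwise Mann–Whitney U with median [IQR] summaries. A group smaller than
3 cannot be tested for normality and falls back to Mann–Whitney with a
logged warning; in the cohort analysis a group smaller than 2 skips the
comparison entirely. Correlations gate Pearson vs Spearman the same way,
per variable, and are flagged significant at the stricter p < 0.001.

The a-priori sample size uses the Walter–Eliasziw–Donner approximation

    n = 1 + 2k (z₁₋α + z₁₋β)² / [(k−1) (ln(C1/C0))²],  C(ρ) = 1 + kρ/(1−ρ),

rounded up. The null ICC is rarely stated in clinical sample-size
paragraphs; the default ρ0 = 0 with a one-sided α is the minimal assumption
that reproduces the standard design numbers (k = 3, α = 0.05, power 0.90,
ρ1 = 0.50 → n = 15; +30% dropout → 20), and both are exposed as
parameters. Dropout inflation rounds n·(1+rate) to 9 decimals before the
ceiling to keep binary-float artifacts from changing the integer answer.

## Synthetic data

The generator models the first-order structure of an osteoarthritic ankle
distance map: a tilted plafond over the dome produces, to first order, a
linear gap gradient, so a field is parameterized by baseline d0 (mm),
gradients gx, gy (mm per normalized rectangle unit), additive Gaussian
noise on square means, and optional cyst squares. Defaults are chosen as
realistic study conditions: d0 = 0.5 mm (joint-space width in contact
regions), per-square noise 0.05 mm (a tenth of the baseline), cohort
gradients ~ N(0, 0.3) (TWS spread of ≈0.023, spanning clearly varus to
clearly valgus patterns), and rater noise 0.002 on TWS — one order of
magnitude below the between-patient spread, the regime in which observed
agreement is excellent. Alignment angles are linear functions of the
deformity plus noise; the coupling signs follow the clinically observed
group directions (valgus feet: higher TSA, HFA, talar tilt; posterior
contact: higher β angle and TTR) and the magnitudes are set so group
contrasts are a few degrees, comparable to published OA cohorts. Reported
correlation tables in the literature are not internally sign-consistent
with those group directions; the generator follows the group directions
and leaves the sign convention overridable per angle.

Mesh-level generation realizes the same field geometrically: the dome is a
planar patch (30 × 35 mm, typical adult dome dimensions) and the plafond is
offset vertically by d(x, y), extended 15% beyond the dome so boundary
vertices see an interior nearest point. Because the offset is applied
vertically while the engine measures perpendicular distance, a gradient g
introduces a relative error of 1 − cos(arctan(g/width)) ≈ 10⁻⁴ at g = 0.4
— far inside the 5% discretization tolerance used for end-to-end checks.
What the planar model deliberately omits: dome curvature, irregular
articular boundaries, osteophyte geometry, and spatially correlated
cartilage loss. Passing tests therefore demonstrate the correctness of the
scoring machinery and its statistical behaviour under the stated model,
not the clinical accuracy of the technique on real anatomy.

## Problem sizes

The verification suite uses 16-square tables (1000 random grids for the
invariance properties, 500 seeded replicates for estimator bias), 5×3
rating tables (200 random tables against the ANOVA oracle), mesh pipelines
at 64×64 dome resolution (≈4k vertices, ≈11k target triangles), and 2000
replicates of n = 20 + 20 null groups for type-I calibration. These sizes
give sampling error well below the tolerances they are checked against
while keeping the whole suite fast enough to run routinely.

## Known limitations

- The nearest-point distance definition is a declared contract, not a
  reverse-engineered match to any clinical software; absolute distance
  values may differ from proprietary pipelines even when patterns agree.
- The normalized-coordinate convention makes TWS dimensionless; studies
  that weighted squares by millimetre offsets would produce size-dependent
  values that are not directly comparable.
- Cyst and osteophyte regions are inputs (vertex labels or flags); no
  detection is attempted.
- The mesh generator's planar dome cannot probe failure modes caused by
  strong curvature, such as oblique nearest-point directions near the
  dome shoulders.
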