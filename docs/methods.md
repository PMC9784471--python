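# Methods

## Contact model

All contact analysis operates on a single fibril chain (protomer) with its
author residue numbering taken verbatim; the tau depositions number
residues on the 2N4R template, so Tyr310 is seq_id 310 everywhere.  Two
contact types are defined purely by atom class and Euclidean distance on
heavy atoms:

* **hydrogen bond** — one hydrogen-bond-donor-capable atom and one
  acceptor-capable atom at ≤ 3.3 Å;
* **hydrophobic** — two apolar carbons at ≤ 5.0 Å.

Both cutoffs are inclusive maxima and configurable (`ContactParams`).
There is no donor–H–acceptor angle term: cryo-EM depositions carry no
hydrogens, so a distance-only criterion is the honest choice.  Donor and
acceptor capability follows standard amino-acid chemistry (backbone N donor
except proline, backbone O/OXT acceptor, TYR OH and HIS ND1/NE2 both, LYS
NZ donor, ASP/GLU carboxylates acceptors, and so on); an apolar carbon is a
carbon not covalently bonded to N or O in the residue template.  CYS SG and
MET SD are included as weak donor/acceptor-capable by default
(`sulfur_hbonds=False` disables this).  A polar pair inside both cutoffs is
reported once, as a hydrogen bond; a polar pair between 3.3 and 5.0 Å is
not a contact of either type, because type membership is atom-class-based,
not distance-based.

Two default exclusions keep the tables informative: pairs closer than 3 in
sequence (`min_seq_separation=3`), because i±1/i±2 proximities are forced
by the chain, and backbone–backbone pairs, because cross-β backbone ladders
are ubiquitous and say nothing about sidechain packing.  Both can be
switched off for audit, which produces a strict superset of any stricter
setting.

The engine uses a k-d tree for candidate search; correctness is defined as
exact set equality with an exhaustive all-pairs scan applying the same
rules, and the test suite asserts this equality on randomized fixtures up
to 200 residues.

## Motifs, strain classes, truncation loss

`scan_motifs` reports every (overlapping) occurrence of a motif in the
modeled one-letter sequence.  An occurrence is *fully resolved* only when
its residues carry consecutive author seq_ids; a motif assembled across a
numbering gap (e.g. across the missing R2 of a 3R-tau fold) is reported
but flagged, and never counts as an ordered core.  A fold is
**single_core** when exactly one of PHF6/PHF6\* is fully resolved,
**dual_core** when both are.

`truncation_loss` removes the last `suffix_len` (default 3) residues of a
resolved hexamer — VYK from VQIVYK, INK from VQIINK — and reports every
residue-pair interaction with at least one member among the removed
residues, excluding pairs internal to the motif: the analysis concerns the
motif's anchoring to the rest of the fold, not its self-packing.
`rank_cores` orders cores by lost-pair count (descending); ties break
alphabetically and are flagged rather than hidden.

## Fold stand-ins

The eight published protofilament folds are represented offline by
synthetic stand-ins generated from a packaged profile table
(`data/fold_profiles.json`).  Per fold the table records the modeled
author-residue range(s) of the ordered core — which alone determines the
strain class, since classification only asks which hexamers are ordered —
and the reported sidechain neighbourhood of the hexamer suffix residues as
planted atom pairs (hydrogen bonds at 2.9–3.1 Å, hydrophobic pairs at
3.9–4.7 Å).  The Pick's-fold stand-in is built with the R2 numbering gap of
3R tau, so VQIINK is genuinely absent from its modeled sequence rather
than merely unlabeled.  Stand-ins exercise exactly the code paths used for
real depositions (structure → protomer → contacts → classification); what
they cannot show is agreement of *full* contact inventories with the real
coordinates — only the planted neighbourhoods are meaningful, and the
package asserts inclusion of the named pairs, never equality of complete
tables.  Real structures can be substituted at any time via
`taucore classify --fetch`.

## Synthetic fixtures

`make_contact_fixture` places residues on a coarse grid whose spacing
exceeds the decoy minimum (default 8 Å) plus the largest planted distance,
jitters atoms within ±0.7 Å of their residue anchor, and then positions
planted atom pairs analytically in a separate grid row.  Construction is
verified: every planted distance to 1 µÅ, and every non-planted
inter-residue pair beyond the decoy minimum; violations (mutually
unsatisfiable distance constraints, cyclic constraint graphs) raise an
explicit construction error rather than emitting a misleading fixture.
The first placement direction is an exact coordinate axis so an isolated
pair realises its distance bit-exactly — a pair planted *at* a cutoff stays
at the cutoff.  Mini fibrils stack chain copies along z at a default rise
of 4.7 Å, the canonical cross-β spacing.  All generation is deterministic
per (spec, seed): identical inputs give byte-identical PDB output.

## Constructs

The domain map (JSON, overridable) tiles 2N4R: N_head 1–44, N1 45–73, N2
74–102, mid 103–150, proline-rich 151–243, R1 244–274, R2 275–305, R3
306–336, R4 337–368, C-tail 369–441, consistent with PHF6\* at 275 and
PHF6 at 306.  Isoforms drop N1/N2 and/or R2; the truncation series use one
cut per internal domain boundary (N-series cuts 45, 74, 103, 151, 244,
275, 306, 337; C-series cuts 368, 336, 305, 274, 243).  The extension
constructs share the C4 carrier (residues 1–274): C6 appends VQIINK, C8
appends VQI, and C7 is realised on the 2N3R parent, where R3 directly
joins R1, cut six residues after the junction so it ends …VQIVYK.
Purification tags are not part of the sequences: they are purification
plumbing, irrelevant to motif logic.

The amyloidogenicity rule — predicted competent iff the sequence contains
an intact VQIVYK or VQIINK — reproduces all recorded C-series, extension
and isoform outcomes (C1–C3, C6, C7 positive; C4, C5, C8 negative; all six
isoforms positive).  The recorded N-series outcomes are attached as labels
but deliberately not scored: under the boundary-derived default cuts N7
starts at 306 and retains PHF6, while the recorded N7 outcome is negative.
The published N-construct endpoints cannot be reconstructed from boundary
logic alone, so the discrepancy is surfaced in every constructs report
instead of being tuned away.

## Kinetics

ThT curves are modelled as y(t) = baseline + amplitude·σ(k(t−t50)) with
σ the standard logistic, fitted by least squares (`scipy.optimize.curve_fit`)
with a deterministic initialisation (baseline = first decile, amplitude =
range, t50 = first half-range crossing, k = 1 /h) and bounds that keep
amplitude non-negative and t50 inside the observed time window, so a
positive call always has an in-range half-time.  The logistic is a
phenomenological stand-in — the minimal sigmoid with an interpretable
half-time — not a mechanistic nucleation–elongation model.  A curve is
called positive iff amplitude ≥ 3 × baseline and the logistic RSS is at
most 0.5 × the flat-model RSS; both thresholds are explicit parameters.
Simulated curves default to amplitude 100, baseline 10, t50 20 h,
k 0.5 /h, Gaussian noise sd 2, over 60 h — within the 40–80 h window real
tau/heparin reactions take to plateau — and noise is additive Gaussian,
the simplest model consistent with plate-reader readouts.  At these
conditions the fit recovers t50 to ≈ 0.04 h mean absolute error and the
call reaches 100 % sensitivity and specificity over 100 + 100 curves (the
acceptance script recomputes this).

What the simulations do not emulate: lag-phase stochasticity between
replicate wells, photobleaching or evaporation drifts, secondary
nucleation kinetics, and amplitude heterogeneity between constructs — so
passing tests demonstrate correct calling on clean sigmoids versus flat
noise, not robustness to every real-plate pathology.

## Problem sizes and numerical choices

Randomized oracle checks run on 50 fixtures of 10–200 residues; kinetic
operating characteristics use 100 positive and 100 flat curves of 200
points; the classification analysis covers all eight folds.  Distances are
double-precision Euclidean; cutoff comparisons use ≤; contact records are
canonically ordered (lower seq_id first) so set comparisons are
well-defined; aggregation reports per-pair hydrogen-bond and hydrophobic
counts with the minimum distance, and `dominant_type` is hbond as soon as
one hydrogen bond is present.  Altloc policy keeps blank/'A' conformers;
hydrogens and waters are dropped on read.  Unknown residues type as 'X' in
sequences and raise in the contact engine unless explicitly ignored.

## Known limitations

* Stand-in folds plant only the *reported* neighbour pairs; the published
  appendix distance tables are not reproduced, so per-pair distance
  agreement with the depositions is out of scope (inclusion, not equality,
  is asserted).
* No inter-protomer (stacking) contacts in the default report; no
  π-stacking, salt-bridge or cation-π classes; no solvent accessibility.
* The modeled residue ranges in the fold profile table are approximations
  of each deposition's ordered core, adequate for core presence/absence
  but not for fold-shape comparisons, which this package does not attempt.
* Construct design is sequence-level only: no codon, primer, expression or
  purification modelling.
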