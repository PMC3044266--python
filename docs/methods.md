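# Methods

## Problem and approach

Disulfide (S-S) bonds between cysteine thiols stabilize protein
structure; mapping which cysteines are bonded from LC-MS/MS data of a
non-reduced digest is a search problem whose naive form is exponential:
the number of connectivity patterns over n bonded cysteines is
n!/((n/2)!·2^(n/2)), and with f fragment-ion types a k-peptide bonded
structure admits up to f^k fragment arrangements.

`sslinker` implements a two-stage matching strategy that never builds
the full search space.  Both stages cast mass-list construction as an
approximate subset-sum problem:

1. **Precursor stage (DMS vs. PMS).**  Cysteine-containing peptides
   (CCPs) from an in-silico digest are combined into disulfide-bonded
   structure masses (sum of peptide masses minus 2·1.00783 Da per
   bond).  The list is grown one CCP at a time — each round adds the
   peptide alone, its intra-bonded form when it has two cysteines, and
   every retained structure extended by the peptide through one more
   bond — discarding masses above `PMS_val + T_IM`, merging with
   duplicates collapsed, and trimming (below).  An *Initial Match* (IM)
   is declared when the largest retained mass lies within `T_IM` of the
   precursor value.
2. **Fragment stage (FMS vs. TMS).**  For each IM the ten backbone ion
   types (a, b, b°, b*, c, x, y, y°, y*, z) are generated for every
   cleavage site of each peptide; fragments that span a bonded cysteine
   remain attached to the partner peptide (intact or itself cleaved),
   fragments on the far side are free.  The resulting fragment-structure
   mass list is trimmed with a parameter delta and matched against the
   MS/MS peaks; a *Validation Match* (VM) is declared per peak by the
   same largest-retained-within-window rule.

Validated bonds are scored, thresholded, and assembled into a globally
consistent topology by maximum-weight matching on the cysteine graph.

## Trimming

`trim` scans an ascending mass list and keeps an element only if it
exceeds the last kept element by more than the factor (1+eps); every
removed mass m therefore has a retained representative m* with
m/(1+eps) <= m* <= m.  Two departures from the textbook scheme matter:

* **The list maximum is never trimmed.**  The match test compares the
  largest retained value against an absolute window; with the exclusion
  cutoff at `target + threshold` the list maximum *is* the candidate
  under test, and thinning it against an interior representative would
  remove exactly the quantity the test inspects.  With this exemption
  the worked-example search (29 CCP masses, eps 0.02530, PMS 2050.5)
  reliably reports its Initial Match at 2050, independent of the CCP
  iteration order.  The exemption costs at most one extra element, so
  the retained length stays within 2 + ln(PMS_val)·(1+eps)/eps.
* **Per-round versus overall guarantee.**  Trimming each merge round at
  the full eps keeps the list within the log_(1+eps) length bound but
  compounds the error over k rounds to (1+eps)^k.  The strict overall
  (1+eps) guarantee requires each round to trim at eps/(2k); this is
  available as `approx_dms(..., scale_epsilon=True)` and is what the
  approximation-soundness tests exercise.  The default follows the
  published per-round behaviour.

Retained-versus-trimmed *membership* is sensitive to the insertion
order of equal-coverage representatives and is not meaningful output;
only the declared matches and the search-space sizes are.

## Match declaration and candidate expansion

Trimming is a computational device, which is why trimmed elements keep
their provenance (the TrimSet).  Declaration follows the largest
retained value, but once a match is declared the candidate structures
are all structures — retained or trimmed — whose exact mass falls
inside the match window.  Candidates are then expanded into concrete
cysteine-pair assignments (every way of wiring the structure's bonds
through distinct cysteines so that all peptides are connected);
assignments that no cysteine arrangement can realize are dropped at
this point.  During list construction, extension is deliberately pure
mass arithmetic: a retained representative must be able to stand in for
a trimmed element under any later extension, so chemical feasibility is
checked only at expansion time.  A VM's mass error (`delta`) is
reported for the best candidate structure in its window, so a peak
placed exactly on a theoretical mass validates with delta 0 even when
the declared representative is a neighbour.

## Scoring

Peak intensities are normalized to the base peak (I_N in (0,1]).  The
bond-level match score is

    V_s = 100 · Σ_i VM_i · I_N(i) / Σ_i TMS_i · I_N(i)

where the numerator counts every (fragment-structure, peak) validation
pair — a peak matched by several theoretical structures contributes
once per match, so V_s above 100 is expected for well-covered bonds —
and the denominator sums the peaks offered for matching (those at or
above the intensity floor; an all-peaks variant is available via
`floor_restricted=False`).

Two confidence surrogates accompany V_s.  `pp` asks whether the match
*count* could be random: with per-peak hit probability
q = min(1, 2·T_VM·|FMS|/mass range), pp = −log10 P(X ≥ n_matched) for
X ~ Binomial(n_peaks, q), computed from the exact binomial tail.  `pp2`
asks whether the matched *abundance* could be random: the −log10
fraction of seeded Monte-Carlo draws (10^4 by default) of equally many
peaks whose I_N total reaches the observed matched total.  Both are
clipped to [0, 300].  These are explicit surrogates for the original
probability model, whose published formulas are not available here;
only their ordering and monotonic behaviour are asserted, never their
absolute values.

Edges with V_s at or above the score threshold (80 for multi-ion
searches, 30 for b/y-only — the stricter cut is what consideration of
all ten ion types buys) enter an undirected graph on the protein's
cysteines, and the reported topology is its maximum-weight matching
(networkx's blossom-class implementation), which enforces that no
cysteine carries two bonds.  Evaluation reports sensitivity Q_c = TP/P,
specificity Q_nc = TN/N, accuracy Q_2 = (TP+TN)/(P+N) and the Matthews
coefficient over an explicit universe of candidate cysteine pairs;
ratios with an empty class are reported as absent rather than 0 or 1.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `t_im` | 1.0 Da | precursor match window; at the smallest worked-example CCP mass (716 Da) this equals 99.86% matching accuracy |
| `t_vm` | 1.0 Da | product-ion match window (not printed in the source study; configurable) |
| `epsilon` | auto | DMS trim ratio; `auto` uses a fitted regression model when configured, else min(0.01, t_im/(2·PMS_val)) |
| `delta` | auto | FMS trim ratio; `auto` analogous with t_vm and the spectrum's mass range |
| `intensity_floor` | 0.10 | fraction of base-peak intensity below which peaks are ignored |
| `score_threshold` | 80 / 30 | V_s cut for multi-ion / b/y-only searches |
| `k_max` | 3 | maximum peptides per bonded structure |
| `missed_cleavages` | 0 | digestion missed-cleavage depth |
| z convention | z-dot | z = y − 16.01872 (classical z − 17.02655 via option) |

The `auto` cap `t_im/(2·PMS_val)` keeps the trimming resolution near
the target finer than the absolute match window: a removed element is
only guaranteed a representative within factor (1+eps), i.e. within
eps·PMS_val daltons, so eps larger than T_IM/PMS_val can in principle
prevent a window candidate from ever being formed.

The epsilon/delta regression machinery (`params`) fits ordinary least
squares on bootstrap-resampled groups of training proteins (groups of
four by default, coefficients averaged over replicates, deterministic
per seed).  The published functional forms and coefficients are not
recoverable from the source, so the package ships the machinery, a JSON
slot for user coefficients, and a single-point calibration fixture
(`ST8SIA4_EPSILON_MODEL`, a constant model pinning eps = 0.02530, the
worked example's operating point).  With neither model nor literal
value, eps = delta = 0.01 applies, subject to the cap above.

## Synthetic data

`simulate_dataset` emulates the study conditions that the original raw
LC-MS/MS data (unavailable) provided: a random tryptic protein built
from 6–11-residue peptides, 2·n_bonds of which carry one bonded
cysteine and one more a free cysteine (so negative pairs exist for
specificity accounting); per planted bond, one neutral precursor mass
(structure mass plus Gaussian noise, default sd 0) and one spectrum
whose peaks are the singly protonated theoretical fragment-structure
m/z values with intensities uniform on [0.2, 1], plus decoy peaks at
uniform random m/z excluded from ±t_vm of every theoretical mass.
Everything is a deterministic function of the seed.

What the simulator does not model — isotope envelopes, charge-state
distributions, peak-shape and intensity physics, retention time,
co-isolation, semi-specific cleavage — bounds what closed-loop tests
show: they validate the search, scoring and topology machinery, not
robustness to real instrument artefacts.  The closed-loop bars (perfect
recovery at zero noise with 1–3 bonds; ≥95% planted-bond recovery at
0.2 Da precursor noise with 20 decoys per spectrum over 50 replicates)
are this package's own acceptance conditions, at desk scale (proteins
of ~7 peptides, two bonds, ~400 true peaks per spectrum).

## Numerical choices and degenerate inputs

* Masses are neutral monoisotopic daltons throughout (the worked
  example's 2050.0 is reproduced only on this scale; average masses are
  an option).  Peaks are read as singly protonated m/z; doubly charged
  interpretation is tested additionally when enabled.
* Masses equal within 1e-6 Da collapse into one list entry with merged
  provenance; ties at a matched mass yield multiple candidates.
* A structure must contain at least one bond; a bond-free peptide mass
  may populate the DMS (as a linkable intermediate) but never declares
  a match by itself.
* An empty CCP list yields an empty mass space and no matches; an empty
  spectrum, a zero score denominator, unsorted trim input, unknown
  residues/enzymes/ion types are rejected with explicit errors.
* Bond-assignment enumeration is capped (200 per structure) to guard
  cysteine-rich pathological inputs; the cap is unreachable on the
  study-scale data.

## Known limitations

* pp/pp2 are surrogates; absolute values are not comparable to the
  original study's tables.
* The intra-bond fragment model covers single-peptide intra bonds
  (looped fragments and two-piece double-cleavage products); intra
  bonds nested inside multi-peptide structures contribute mass
  bookkeeping only.
* No PTM search, isotope-cluster matching, internal/immonium ions,
  FDR estimation, or mzML input.
* With T_VM at its 1.0 Da default and monoisotopic fragment masses
  lying near the ~1 Da residue lattice, peak-level discrimination
  between candidate bonds is partly carried by the score threshold and
  the global matching stage; tighter instruments warrant a smaller
  T_VM.
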