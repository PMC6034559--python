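# Methods

This note records the models, parameter choices and numerical
conventions behind `raretaxa`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Marker discovery

**Model.** The target taxon is represented by a reference genome and an
inclusion clade (other genomes of the same taxon); near relatives that
must not cross-react form the exclusion clade. Homology is scored by
Smith–Waterman local alignment with linear gap costs (match +1,
mismatch −1, gap −2), both strands searched, in a numba-compiled
kernel. A hit reports the maximal alignment's score, percent identity
over aligned columns (gap columns included), and query coverage
(aligned query span / query length).

**Determinism.** Co-optimal alignments are resolved by a fixed
convention: traceback starts at the first maximal cell in row-major
order and prefers diagonal over up over left. Best hits within a genome
break score ties by plus strand, then lexicographically smaller gene
id, so all outputs are independent of input order.

**Thresholds.** Conservation requires identity ≥ 70% and coverage
≥ 70% in *every* inclusion genome; exclusion subtraction fires on
identity ≥ 50% and coverage ≥ 50% in *any* exclusion genome. All four
cutoffs are explicit keyword arguments — there is no community-standard
value for "homologous enough", so they must be visible and overridable.

**Minimum-score floor.** A threshold-passing hit must additionally
score ≥ 0.2 × query length (`min_score_frac`). The maximal local
alignment between two unrelated random genes occasionally follows a
long, gappy, barely-positive path whose column identity and coverage
clear the percent cutoffs even though its score is within the noise
tail (tens of points for 300 bp genes); a genuine homolog at the
threshold identities scores a large fraction of the query length under
+1/−1/−2, so the floor separates the regimes without touching real
hits. Note also that under this scoring a 50 %-identity homolog has
expected score ≈ 0 and is intrinsically invisible to local alignment;
the exclusion cutoffs therefore act on much-better-than-50 % relatives,
which is what the subtraction step is for.

**Word seeding.** The all-vs-all scans skip alignments between gene
pairs sharing no exact 11-mer on the tested strand (per-genome k-mer
indexes are precomputed). Any alignment that could pass the thresholds
contains long exact runs, so seeding cannot drop a qualifying hit at
realistic word sizes; `seed_word_size=None` restores the exhaustive
scan. `align_local` itself is always exact.

**Ranking.** conservation_score = mean over inclusion genomes of
(identity/100 × coverage/100), a number in [0, 1]; genomes without a
hit contribute 0. Ties in the top-k selection break by gene id.

## Primer design and in-silico PCR

The designer enumerates every primer window satisfying length 18–25 nt,
GC 40–60 %, Wallace-rule Tm = 2(A+T) + 4(G+C) within 55–62 °C, pairs
them under product length 80–300 bp and |ΔTm| ≤ 3 °C, and ranks by the
additive penalty |ΔTm| + mean GC deviation from 50 % + product-length
deviation from the 150 bp optimum. The Wallace rule was chosen over
nearest-neighbor thermodynamics because it is closed-form and exactly
testable; the penalty is deliberately simple and is this package's own
definition, not a reimplementation of Primer3's objective. Degenerate
IUPAC bases are rejected rather than expanded.

In-silico PCR reports every site where the forward primer matches one
strand and the reverse primer matches the other strand downstream,
within 3000 bp (a bound on scan cost), allowing a configurable number
of mismatches per primer but always requiring the 3′-terminal base to
match exactly — polymerase extension is most sensitive there. Verdicts:
*specific* (≥ 1 amplicon in every inclusion genome, none in exclusion),
*non_universal* (missing somewhere in inclusion), *non_specific* (any
exclusion amplicon; this verdict takes precedence). Coordinates are
0-based half-open throughout; minus-strand hits are reported in
plus-strand coordinates.

## qPCR quantification

Standard curves are ordinary least squares of Ct on log₁₀(copies)
(slope must be negative; efficiency 10^(−1/slope) − 1). Unknowns invert
through the fitted line; extrapolation outside the fitted copy range is
allowed but flagged. Copies-per-reaction convert to CFU/ml via a single
user-supplied factor (default 1) — extraction volumes and per-genome
copy numbers vary by assay and should not be hidden constants.
Replicate Cts are averaged (median optional) before inversion.

Positivity uses the 10⁴ CFU/ml detection threshold, boundary inclusive,
with a 10⁻⁹ relative guard so a load exactly at the threshold cannot
flip negative from the ~10⁻¹³ relative float error of the log/power
round trip. The companion constant of ~10⁵ organisms in a ~10¹¹ total
community is exposed separately (`DETECTION_LIMIT_ORGANISMS`,
`TOTAL_MICROBIOTA_CFU_PER_ML`) and deliberately not reconciled with the
CFU/ml figure, since the two are stated on different scales.

Relative expression is 2^−(Ct_target − Ct_reference) against actin.

The detectability calculator assumes reads land uniformly
(Lander–Waterman): a taxon at relative abundance *a* in *D* sequenced
bases covers fraction 1 − e^(−aD/L) of its genome of length *L*, so
the minimum abundance reaching covered fraction *f* is
a\* = −L·ln(1−f)/D. At D = 4×10⁹, L = 1.6×10⁶, f = 0.01 this gives
4.0×10⁻⁶ — a taxon at 10⁴/10¹¹ ≈ 10⁻⁷ is an order of magnitude below
what that sequencing depth can see, which is the quantitative content
of "4 GB was not sensitive enough".

## Peptide evidence

Trypsin cleaves C-terminal to K or R except before proline (the KP rule
is consistent with all 18 shipped reference peptides). Digestion emits
all peptides with ≤ 2 internal missed cleavage sites (non-C-terminal
K/R not followed by P) and length ≥ 4; masses are monoisotopic residue
sums plus one water (via pyteomics); precursor matching uses an
inclusive ±15 ppm window. Uniqueness is exact substring containment:
a short peptide matched at 100 % identity over its full length *is* a
substring, so heuristic alignment (BLAST in the original workflow)
reduces to a deterministic search. N-terminal methionine is not
clipped, and I/L are distinct residues — the uniqueness claim is made
at the sequence level; both behaviors are overridable at call sites by
preprocessing the proteomes.

## Synthetic data

One root seed; each generator draws from its own stream
(`default_rng([seed, offset])` with fixed offsets), so generators are
pure functions of (config, seed) and adding a stage never perturbs the
others.

* **Pan-genome** (defaults: 5 inclusion genomes, 3 exclusion genomes,
  30 reference genes of 300 bp, 12 conserved, 4 exclusion-shared,
  point-mutation rate 0.02). Genes are uniform random ACGT; planted
  copies receive i.i.d. substitutions (no indels by default, an
  indel-rate option exists), random orientation, opaque ids and
  shuffled order, so recovery must come from alignment, not labels.
  The sizes are desk-scale stand-ins for the real 10-genome/
  1500-gene problem, chosen so a full discovery run takes well under a
  second; 2 % divergence keeps planted copies near the upper end of
  within-taxon strain divergence while remaining clearly above the
  conservation cutoffs.
* **sIgA cohort** (23 positive / 24 negative subjects). Concentrations
  are positive and right-skewed, so each group is log-normal with
  log-median ln(median) — medians 118.60 and 69.21 μg/ml, the published
  group medians — and log-sd 0.4, this package's choice: the source
  reports an ambiguous "median ± SEM ± SEM" double interval whose
  meaning is not guessed, and 0.4 gives the ~2-fold interquartile
  spread typical of mucosal immunoglobulin titers. Ages are integer
  months uniform on 8–48 so the closed prevalence bins always cover
  them.
* **qPCR runs.** Curve points at 10¹–10⁷ copies (triplicate) and sample
  Cts from Ct = 37 + (−1/log₁₀2)·log₁₀(copies) + N(0, 0.15) — a
  perfect-efficiency assay with realistic replicate scatter. True loads
  default to log-uniform 10⁴–10⁶ CFU/ml for positives (the observed
  colonized range) and 10²–10⁴ for negatives.
* **Proteomes.** Each planted peptide is embedded so trypsin releases
  it exactly (preceding residue K/R, following residue not P, with
  N/C-terminal placement for peptides that cannot be flanked).
  Background proteins are grown residue-by-residue avoiding every
  4-mer of the inclusion proteome, which makes "no shared peptide of
  length ≥ 4" a construction guarantee; deliberately planted shared
  decoys exercise the non-unique branch.
* **Abundance tables.** Dirichlet draws per group with concentration
  multipliers on the taxa reported to shift with colonization
  (Clostridia, Coriobacteriia, Deltaproteobacteria up when colonized;
  Bacteroides, Escherichia, Klebsiella up otherwise), the non-colonized
  group concentrating more mass and hence showing lower Shannon
  diversity.

**What passing tests show — and don't.** Planted-truth recovery shows
the discovery, uniqueness and quantification logic is correct under the
stated noise models. Real pan-genomes have paralogs, mobile elements,
indels and compositional bias; real proteomes share conserved domains
with the background; real qPCR has inhibition and efficiency drift.
None of those are modeled, so passing here validates the algorithms,
not field performance of any particular assay.

## Cohort statistics

Prevalence uses the published closed age bins (0–36, 37–72, 73–108,
109–181 months), floors fractional ages to whole months, reports
percentages rounded to 2 decimals, and reports an empty bin as missing
rather than 0 %. Prevalence is always computed from the underlying
counts. The default two-group test is Student's t (the source's
choice) with Welch and Mann–Whitney one flag away, since concentration
data are skewed. BH adjustment is the standard step-up (via
statsmodels), order-preserving and capped at 1. Differential selection
keeps genes with ≥ 2-fold change in either direction and adjusted
p < 0.05, both boundaries as stated (fold inclusive, alpha exclusive).
Shannon diversity uses natural log by default with a base option.

## Pipeline and reproducibility

`run_pipeline` executes simulate → discover → design/validate primers →
quantify → digest/uniqueness → cohort statistics, writing five CSVs and
a JSON manifest (package version, seed, full parameter set, SHA-256 of
every output). The manifest contains no wall-clock timestamp and no
absolute paths, so identical (config, seed) reruns are byte-identical.
A failing stage writes a `FAILED` marker and aborts with a
stage-labeled error, keeping partial outputs for inspection.

## Known limitations

* Local alignment is score-exact but single-best: co-optimal
  alignments with different identities are resolved by convention, not
  enumerated.
* The Wallace Tm rule is crude for oligos far from 20 nt; a
  nearest-neighbor model is the natural extension point.
* The primer designer enumerates a single template at a time and does
  not check cross-dimers or hairpins.
* Exclusion subtraction is existential ("any genome"), so one
  contaminated exclusion genome removes a marker permanently.
* The detectability calculator ignores read length, mappability and
  GC bias; it is a lower bound on the true required abundance.
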