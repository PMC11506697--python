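# tractstage

Event-based subtype-and-stage modelling of white-matter tract damage from
tract-level fractional anisotropy (FA).

## What problem this solves

Cross-sectional diffusion MRI studies of unilateral temporal lobe epilepsy
(TLE) show widespread white-matter disruption, but a single scan per
patient does not directly reveal *in what order* tracts are damaged or *how
far along* an individual patient is. `tractstage` answers both questions
with an event-based progression model: given mean FA in the 20 JHU-atlas
tracts for a patient cohort and a healthy-control reference, it

1. converts FA to healthy-control-referenced **abnormality z-scores**
   (age/sex-corrected, sign-flipped so larger = more damaged) and relabels
   paired tracts into **ipsilateral/contralateral** space around each
   patient's epileptic focus;
2. fits a **linear z-score subtype-and-stage model**: each ROI crosses
   abnormality thresholds z ∈ {1, 2, 3} (N = 60 events); a subtype is an
   ordering S of all events, and a patient at stage k ∈ {0, …, N} has
   expected abnormality g_b(k), the piecewise-linear curve through (0, 0),
   (pos_S(b, z), z) and (N, z_max). Subjects are Gaussian around the
   trajectory with stage marginalized under a uniform prior:

       L(x | S) = (1/(N+1)) Σₖ Πᵦ N(xᵦ; gᵦ(k), σᵦ);

3. optimizes S by multi-start coordinate ascent, quantifies ordering
   uncertainty by Metropolis **MCMC over valid sequences** (positional-
   variance diagrams), selects the number of subtypes by a 10-fold
   **cross-validation information criterion** (CVIC = −2 × held-out log
   likelihood), and assigns each patient a **maximum-likelihood stage**;
4. relates stages to clinical variables (χ², Mann–Whitney U, Spearman —
   the exact conventions that reproduce published TLE demographic tables).

Because tract-level FA datasets are rarely shareable, the package includes
a first-class **synthetic cohort generator** that inverts the model with
known ground truth (planted sequences, stages, and stage-coupled clinical
covariates), so the whole pipeline is testable end to end without any MRI
data. Intended users: imaging neuroscientists and biostatisticians running
or evaluating staging analyses of tract-level DTI summaries.

## Worked example

```python
import tractstage as ts

# synthetic study conditions: 270 controls, 155 unilateral-TLE patients
table, truth = ts.generate_cohort(ts.CohortConfig(seed=7))

hc, patients = table[table.group == "HC"], table[table.group == "TLE"]
norm = ts.CovariateNormalizer().fit(hc)            # normative age/sex model
zmat = ts.lateralize(norm.transform(patients), patients)

model = ts.SubtypeStageModel(n_subtypes=1, n_starts=4,
                             mcmc_iter=20_000, random_state=101).fit(zmat)
print(model.sequence_labels()[:4])
stages = model.predict_stages(zmat)
report = ts.build_association_report(stages, patients)
print(report.to_text())
```

The fitted sequence starts

```
['SLF_ipsi:z1', 'UF_ipsi:z1', 'Forceps_major:z1', 'Forceps_minor:z1']
```

i.e. the model reads the earliest damage in the ipsilateral uncinate and
superior longitudinal fasciculi and the forceps — the trajectory planted
by the generator, recovered at Kendall tau 0.915 between fitted and planted
orderings and Spearman 0.978 between true and maximum-likelihood stages.
The association report prints, among others,

```
        etiology: HS 38.5 (23.75) vs NL 24 (27.5)  U=3435  p=8.08e-05  (n=155)
  duration_years: rs=+0.301  p=0.000141  (n=155)
          n_asms: rs=+0.351  p=1.01e-05  (n=151, missing=4)
```

— HS patients sit at later stages (median 38.5 vs 24) and stage tracks
disease duration and medication load at the planted effect sizes (rank
correlations ~0.3); four patients have missing ASM counts and are dropped
pairwise.

Command-line equivalents: `tractstage simulate | preprocess | fit | stage |
associate | run-all` (see `tractstage --help`); `run-all` writes every
artifact plus a manifest with SHA-256 hashes, and identical configurations
reproduce identical hashes.

## Layout

```
src/tractstage/
  cohort.py       synthetic cohorts with planted ground truth
  preprocess.py   CovariateNormalizer, lateralize (FA -> abnormality z)
  events.py       z-score events, sequences, trajectories
  likelihood.py   stage-marginalized Gaussian likelihood
  fitting.py      greedy ascent, MCMC, positional density
  model.py        SubtypeStageModel, select_n_subtypes (CVIC)
  stats.py        chi-square / Mann-Whitney / Spearman battery
  pipeline.py     run_pipeline with manifest + hashes
  cli.py          click CLI
docs/methods.md   model, assumptions, parameters, limitations
```
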