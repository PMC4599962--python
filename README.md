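# surnamebias

Quantifying sampling selection bias in surname-based recruitment for human
population genetics.

## The problem

Y-chromosome studies routinely recruit donors through surnames: because
family names and MSY markers co-segregate patrilineally in Western naming
practice, a surname is a cheap proxy for a male lineage. But the present-day
surname list of a community is not its founding list — centuries of drift,
immigration and name innovation have reshuffled it — so every recruitment
strategy carries a *sampling-dependent bias* (SDB): the fraction of sampled
units whose surname is **not** attested in the community's oldest historical
record,

```
SDB = 1 − shared_units / n_units ∈ [0, 1]
```

where a *unit* is a surname type under the **low-kinship (LK)** model (one
donor per surname, donors maximally unrelated) or an individual bearer under
the **high-kinship (HK)** model (all bearers of selected surnames count).
SDB = 0 means full adhesion to the founding distribution; SDB = 1 means no
overlap at all.

The package implements, as a tested reusable pipeline:

- **Repertoires** — surname frequency lists per community and era, with
  rule-driven lemmatization (orthographic corrections, compound reduction),
  CSV/TSV/XLSX readers and writers, and the metadata of the 26 Italian study
  communities (years 1447–2001) it was designed around;
- **five sampling strategies** — random (R), locally spread (LS), first
  quartile (FQ), grandparents (GP) and founding surnames (FS, the SDB = 0
  reference) — each under LK and HK;
- **bias and diversity statistics** — SDB, ΔSDB = SDB_LK − SDB_HK, random
  isonymy (unbiased estimator Σnᵢ(nᵢ−1)/N(N−1)), S/N;
- **a patrilineal drift simulator** — neutral Wright–Fisher transmission of
  surnames from foundation to present under growth or stationary size
  models, with innovation and immigration knobs, to estimate how much SDB
  lineage sorting alone would produce;
- **resampling statistics** — delete-d jackknife of fixed donor numbers
  (20/50/100 × 201 replicates), source-comparison tests (R², chi-square
  homogeneity), per-covariate OLS regressions with Bonferroni adjustment;
- **a synthetic-community generator** — linked founding/mid-era/present
  repertoires with known ground truth (immigrant-descent fraction, surname
  class labels) so every stage is testable without archival data.

## Worked example

```python
from surnamebias import (
    Repertoire, select_random, select_founders, sdb, delta_sdb, isonymy,
    DriftParams, simulate_community,
)

historical = Repertoire("Careggine", 1566, "marriage",
                        {"PELLEGRINI": 8, "BERTOZZI": 5, "POLI": 3, "VITI": 2})
present = Repertoire("Careggine", 1993, "phonebook",
                     {"PELLEGRINI": 12, "POLI": 6, "FERRARI": 4, "VITI": 2, "ROSSI": 1})

lk = sdb(select_random(present, "LK", "all"), historical)
hk = sdb(select_random(present, "HK", "all"), historical)
print(f"SDB (random census, LK): {lk.sdb:.3f}  ({lk.shared_units}/{lk.n_units} types shared)")
print(f"SDB (random census, HK): {hk.sdb:.3f}  ({hk.shared_units}/{hk.n_units} bearers shared)")
print(f"delta-SDB (LK - HK):     {delta_sdb(lk, hk):.3f}")

fs = select_founders(present, historical, "HK")
print(f"FS selection: {sorted(fs.types)} -> SDB = {sdb(fs, historical).sdb:.1f}")
print(f"isonymy of the present list: {isonymy(present).isonymy:.4f}")

params = DriftParams(founding=historical, years=427, size_model="growth",
                     final_size=present.n, immigration_rate=0.05,
                     iterations=100, seed=1)
res = simulate_community(params)
print(f"drift-expected SDB (m=0.05/gen): mean {res.mean_sdb:.3f}, "
      f"90% interval {res.interval90[0]:.3f}-{res.interval90[1]:.3f}")
```

prints

```
SDB (random census, LK): 0.400  (3/5 types shared)
SDB (random census, HK): 0.200  (20/25 bearers shared)
delta-SDB (LK - HK):     0.200
FS selection: ['PELLEGRINI', 'POLI', 'VITI'] -> SDB = 0.0
isonymy of the present list: 0.2933
drift-expected SDB (m=0.05/gen): mean 0.740, 90% interval 0.500-1.000
```

Reading: two of the five present-day surnames (FERRARI, ROSSI) are not in
the 1566 marriage acts, so an unrelated-donors (LK) random sample is 40%
biased; admitting multiple bearers per surname (HK) weights the sample
toward the old, still-numerous families and halves the bias. Restricting
recruitment to founding surnames (FS) removes it entirely. The drift
simulation shows that on a toy population this small (N₀ = 18), lineage
sorting plus a 5%-per-generation immigration stream over 14 generations
would by itself push the expected LK bias to ~0.74 — observed biases must
be read against that drift-plus-migration expectation, not against zero.

The same stages are available from the shell:

```bash
surnamebias synth --n-communities 26 --seed 1 --out data/
surnamebias run --config study.yaml          # full report bundle
surnamebias sdb data/SYN01_present.csv data/SYN01_founding.csv \
    --strategy R --model LK
```

`run` writes a tidy bundle: per-community bias results, min/mean/max SDB per
strategy and model, S/N and isonymy summaries, drift comparison, jackknife
summaries and the covariate regression table with Bonferroni-adjusted
p-values.

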