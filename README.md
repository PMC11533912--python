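# tapdose

Internal dosimetry and preclinical analytics for ²¹²Pb targeted alpha
therapy, built around the evaluation of a ²¹²Pb-labeled GRPR-targeting
peptide (GRPR: gastrin-releasing peptide receptor, overexpressed in
prostate and other cancers, physiologically expressed in pancreas).

It is aimed at radiopharmaceutical scientists who need to turn
gamma-counter organ data into human-projected, RBE-weighted absorbed doses
and the associated safety quantities, alongside the standard preclinical
endpoints (binding affinity, survival, radiochemical purity).

## What it computes

* **Decay-chain physics** — the ²¹²Pb → ²¹²Bi → (²¹²Po / ²⁰⁸Tl) → ²⁰⁸Pb
  chain via the analytic Bateman solution, decay correction of counts, and
  per-parent-decay emission energies (E_α = 7.80, E_e = 0.86,
  E_γ = 1.46 MeV at equilibrium).
* **Biodistribution** — percent injected dose per gram,
  %ID/g = 100·counts/(standard/standard_fraction)/mass with both counts
  decay-corrected to injection; group summaries, Welch t contrasts,
  specific-activity effects, tumor-size correlations, chromatogram purity.
* **MIRD-style dosimetry** — time-integrated activity coefficients (TIAC,
  trapezoid + physical-decay tail), mouse→human projection by the
  relative-concentration method, and dose coefficients
  D_o = TIAC_o·(RBE·E_α + E_e + φ·E_γ)/m_o (Gy/GBq), with dose tables,
  limiting-organ activity limits and safety margins.
* **Binding** — one-site saturation fit B(c) = Bmax·c/(Kd + c) after
  nonspecific subtraction, with Jacobian standard errors.
* **Outcomes** — caliper tumor volumes, Kaplan–Meier survival (median =
  earliest t with S(t) ≤ 0.5), humane-endpoint rules.
* **Synthetic data** — seeded generators reproducing the study designs
  (5 animals/timepoint biodistribution with pancreas self-blocking,
  triplicate 0.5–64 nM plates, Weibull survival cohorts, two-peak
  chromatograms) so the full pipeline is testable without animal data.

See `docs/methods.md` for models, assumptions and defaults.

## Worked example

Simulate a study and push it through the dosimetry pipeline:

```bash
tapdose report --seed 1 --out out/
cat out/run_log.json
```

```json
{
  "activity_limit_gbq": 2.551367732289389,
  "kd_nm": 4.145710025625503,
  "limiting_organ": "kidneys",
  "radiochemical_purity_pct": 95.93436223514497,
  "se_kd_nm": 0.23461480240409768,
  "seed": 1
}
```

Reading this: from the synthetic biodistribution the kidneys come out
dose-limiting (as in the real study); the 23 Gy kidney threshold for this
simulated kinetic profile is reached at 2.55 GBq; the fitted Kd of
4.15 ± 0.23 nM brackets the generator's true 3.93 nM; and 95.9 % of
chromatogram counts sit in the main peak of a plate generated at 96 %
purity. `out/dose_table.csv` holds the organ × activity dose grid and
`out/survival_summary.csv` the per-group Kaplan–Meier medians (e.g. the
buffer-only control cohort at 8.3 weeks for this seed, generated at a
9.4-week median).

Individual stages are available as `tapdose simulate`, `tapdose biodist`,
`tapdose dose`, `tapdose binding` and `tapdose survival`, e.g.

```bash
tapdose simulate biodist --preset study --seed 1 --out in/
tapdose dose --biodist in/biodist.csv --phantom human_female --rbe 5 \
             --activities 0.111,0.555,1.110 --group 28ng --out out/
```

The same functionality is importable (`tapdose.dosimetry`,
`tapdose.binding`, ...) for notebook use.

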