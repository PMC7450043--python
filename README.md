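# nascentfret

Analysis pipeline for donor-quench FRET measurements of ribosome-nascent-chain
(RNC) folding, built around the CFTR NBD1 cotranslational compaction assay,
plus a generative simulator of the assay so every stage can be verified
round-trip against closed-form oracles.

## The measurement

Cotranslational folding of CFTR's first nucleotide-binding domain (NBD1) is
probed on stalled ribosome-nascent-chain complexes: a CFP donor is fused
N-terminally and a small acceptor dye is placed at an internal CFTR residue
(Arg487, Asp567, or the Thr389 tether control) by amber suppression. Chain
compaction brings donor and acceptor together, quenching CFP. Each
measurement is a *matched quadruple* of cell-free translation reactions —
donor only (D), donor + acceptor (DA), and two non-fluorescent blanks (BD,
BDA) — with a ¹⁴C-lysine label delivered by the same suppressor tRNA, so
counts report only chains that read through the amber codon.

Per quadruple the pipeline computes:

1. **Peak intensity** — mean of the five highest emission intensities
   (λex 430 nm, λem 450–600 nm at 1 nm; peak ≈ 475 nm).
2. **Concentration** — `[RNC] = (cpm_S − cpm_B) / (CE · SA · vol)` in nM
   from scintillation counts (CE: counting efficiency, SA: specific
   activity in dpm/pmol, vol in ml).
3. **Net fluorescence per nM** — `F = (peak_sample − peak_blank) / [RNC]`,
   D corrected by BD, DA by BDA.
4. **FRET efficiency** — `E = 1 − F_DA / F_D`.
5. **Readthrough QC** — quadruples whose D/DA readthrough ratio falls
   outside the probe-site band (0.80–1.20 for Arg487, 0.85–1.15 for
   Asp567) are flagged: mismatched amber suppression leaves different
   fractions of stalled, zero-FRET chains in D and DA and biases E.

The stall artifact has a closed form. With stall-to-readthrough ratios
`s_D`, `s_DA`, the apparent efficiency is

```
E_app = 1 − ((1 − E_chain) + s_DA) / (1 + s_D)
```

which reduces to `E_chain / (1 + s)` for matched stalls. The simulator
(`nascentfret.synthetic`) generates spectra and counts from this model, so
the measurement pipeline can be checked against the oracle to 1e−6 in the
noise-free limit, and against reported condition means under the study's
noise level (2% spectral CV, Poisson counts, n = 4 replicates).

Downstream analyses mirror the study design: per-condition mean ± SEM,
pooled-variance Student's *t* contrasts of wild type vs mutant (A455E,
L558S, suppressor-rescue constructs), per-truncation length scans with
folding-window detection, bound-vs-released comparisons that enforce
exit-tunnel exposure equivalence (~30–40 sequestered residues), thermal
denaturation difference curves (4–50 °C), and band B/C immunoblot
maturation relative to wild type.

## Worked example

```python
import nascentfret as nf

truth = nf.reference_truth_table()          # packaged study conditions
params = nf.GenerativeParams()              # matched stalls 0.1, 2% noise

profiles = {}
for construct in ("WT", "A455E"):
    key = nf.ConditionKey(construct, probe_site=487, truncation=654)
    bundles = nf.simulate_experiment_series(key, truth, n=4, seed=42,
                                            params=params)
    results = [nf.compute_experiment_fret(b) for b in bundles]
    profiles[construct] = nf.aggregate_profile(results)
    p = profiles[construct]
    print(f"{construct}: {p.mean:.1%} ± {p.sem:.1%} (n={p.n})")

cmp = nf.compare_conditions(profiles["WT"], profiles["A455E"])
print(f"ΔE = {cmp.difference_of_means:.1%}, t = {cmp.t_statistic:.2f}, "
      f"p = {cmp.p_value:.2g}")
```

Output:

```
WT: 39.8% ± 0.6% (n=4)
A455E: 32.6% ± 0.8% (n=4)
ΔE = 7.2%, t = 7.09, p = 0.0004
```

The truncation-654 folding intermediate shows the A455E mutant ~7 FRET
points less compact than wild type — the mutation's maximal de-compaction —
and the two-tailed pooled *t* test calls the difference significant.

The same flows are available from the shell:

```sh
nascentfret simulate --out run/              # reference scenario
nascentfret fret --bundles run/bundles --out run/results.tsv
nascentfret window run/results.tsv --mutant A455E
nascentfret report --seed 1 --out run/       # full pipeline + manifest
```

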