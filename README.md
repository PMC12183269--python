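# endosym

Quantifying what native fungal endophytes contribute to quinoa's salinity
tolerance, and how that contribution varies with the latitude a genotype
originates from.

Quinoa (*Chenopodium quinoa*) is a facultative halophyte whose local
populations span a steep environmental gradient — from the hypersaline
Salares of the Atacama region (~19 °S) to temperate coastal Lowlands
(~39 °S). The habitat-adapted-symbiosis hypothesis predicts that the native
endophytic microbiome of northern, salt-exposed ecotypes contributes mostly
*stress tolerance*, while in southern ecotypes it contributes mostly *seed
productivity and quality*. `endosym` implements the full quantitative
analysis of a factorial greenhouse experiment testing this: plants with
(E+) and without (E−) their native endophytes, at 0 / 200 / 400 mM NaCl,
across five genotypes of known latitudinal origin.

The package covers:

- **Synthetic experiment generator** — the full factorial design (5
  genotypes × 2 symbiotic statuses × 3 NaCl levels × 12 replicate plants =
  360 plants; 5 qPCR biological replicates per condition) with
  latitude-dependent endophyte effect sizes and trait-appropriate noise
  models, so the entire pipeline is testable without any external data.
- **qPCR relative expression** of the vacuolar Na⁺/H⁺ antiporter gene
  *CqNHX1* against the *EF-1α* housekeeping gene, by both the Livak
  2^−ΔΔCt method and the Pfaffl efficiency-corrected ratio
  E_t^ΔCP_t / E_r^ΔCP_r.
- **Trait derivation** — Fv/Fm = (Fm − F0)/Fm from dark-adapted chlorophyll
  fluorescence, survival % = 100·S/N, ISTA-style thousand-seed weight
  (10 × mean mass of 100-seed samples), and Bradford protein via a linear
  BSA standard curve.
- **The composite index** — the Plant Response of a group,

      PR = 0.3·(Fv/Fm) + 0.3·(TSW/10) + 0.3·(survival/100) + 0.1·(protein/10),

  and the Relative Endophyte Contribution Index,

      RECI (%) = (PR_E+ − PR_E−) × 100,

  per genotype × salinity. Positive RECI means the endophytes improved the
  composite response; values near 0 mean they contributed little.
- **Latitudinal trend inference** — least-squares slopes of each response
  against latitude of origin (on genotype-level means) per endophyte ×
  salinity group, pairwise slope contrasts with Holm adjustment and a
  compact letter display, and a cluster-respecting permutation test of the
  E+/E− slope difference that reshuffles symbiotic-status labels only
  within genotypes.

## Worked example

```python
from endosym import StudyDesign, simulate_dataset, summarize_plants
from endosym.reci import reci_table

data = simulate_dataset(StudyDesign(seed=1), seed=1)
summary = summarize_plants(data["plants"])
table = reci_table(summary)
print(table[["genotype", "latitude_deg_s", "nacl_mM",
             "pr_eplus", "pr_eminus", "reci_pct"]].round(3).to_string(index=False))
```

prints

```
genotype  latitude_deg_s  nacl_mM  pr_eplus  pr_eminus  reci_pct
    BO78            39.0      0.0     0.680      0.686    -0.681
    BO78            39.0    200.0     0.606      0.592     1.346
    BO78            39.0    400.0     0.468      0.452     1.536
     PRP            34.0      0.0     0.656      0.663    -0.681
     PRP            34.0    200.0     0.629      0.596     3.350
     PRP            34.0    400.0     0.472      0.420     5.219
Paihuano            29.0      0.0     0.680      0.637     4.289
Paihuano            29.0    200.0     0.650      0.548    10.124
Paihuano            29.0    400.0     0.500      0.348    15.219
 Pandela            19.0      0.0     0.704      0.710    -0.588
 Pandela            19.0    200.0     0.688      0.643     4.496
 Pandela            19.0    400.0     0.634      0.392    24.236
   UdeC9            35.0      0.0     0.709      0.687     2.175
   UdeC9            35.0    200.0     0.584      0.566     1.717
   UdeC9            35.0    400.0     0.518      0.381    13.694
```

Read this as: under non-saline control conditions the endophytes are close
to neutral everywhere (RECI within a few points of 0), while under severe
salinity stress (400 mM) their contribution is largest for the northernmost
Salares genotype Pandela (≈ 24 percentage points of composite Plant
Response) and smallest for the southern Lowlands genotypes — the clinal
pattern the index was designed to expose.

The same analysis runs end to end from the shell:

```bash
endosym run-all --out runs/demo --seed 1
endosym simulate --out sim/ --seed 2
endosym quantify --in sim/qpcr.csv --out expr.csv --method pfaffl
endosym summarize --in sim/plants.csv --out summary.csv
endosym score --in summary.csv --out reci.csv
endosym trend --in summary.csv --response survival --out trend/
```

`run-all` writes every intermediate table (plants, Ct values, expression,
group summary, RECI, slopes, contrasts, letters, permutation tests), a
`report.md`, a RECI bar figure, and a provenance manifest; reruns with the
same config are byte-identical.

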