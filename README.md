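# epiqtl

Interval mapping of **pairs of interacting, multiallelic QTLs** in a
full-sib family derived from two outbred (heterozygous) parents — the
standard situation in forest trees and other outcrossing species where
inbred-line designs are impossible.

## The model

With parents P1 (alleles 1/2) and P2 (alleles 3/4), each QTL segregates
into four offspring genotypes 13, 14, 23, 24. For two QTLs the 16
two-locus genotypic values decompose orthogonally into 16 effects

u = D a,  a = (μ, α₁, β₁, γ₁, α₂, β₂, γ₂, I_αα, I_αβ, I_βα, I_ββ, J_αγ, J_βγ, K_γα, K_γβ, L_γγ)ᵀ,

where α/β are additive effects of the P1/P2 allele substitutions, γ the
within-locus dominance, and I/J/K/L the additive×additive,
additive×dominance, dominance×additive and dominance×dominance epistatic
components split by parental origin. **D** is a ±1 orthogonal design
matrix (DᵀD = 16 I), so effects and genotypic values are an exact
bijection and each effect has a balanced ±1 contrast on **u**.

Phenotypes follow a 16-component normal mixture: the mixture weights
ω are the probabilities of the two-locus QTL genotypes given the
flanking fully informative markers (Haldane map function, no
interference, known linkage phases). The mixture is fitted by EM with
closed-form M-steps; a 2-D grid scan of position pairs maximises the
likelihood-ratio statistic LR = 2(lnL₁ − lnL₀) against the no-QTL
single-normal null, with significance thresholds from phenotype
permutations. Each of the 15 effects is then tested by refitting the
mixture under the single linear constraint cᵀu = 0 that zeroes it.

## Worked example

```sh
epiqtl simulate --preset benchmark --n 2000 --h2 0.4 --seed 17 --out fam/
epiqtl scan --map fam/map.tsv --geno fam/genotypes.tsv \
            --pheno fam/phenotypes.tsv --groups LG1,LG1 --step 2 \
            --out results.tsv
```

prints

```
best pair LG1:32 x LG1:70 LR=567.6316
```

i.e. the scan localises the two simulated QTLs to within one grid step
of the truth (30 and 70 cM on a 100 cM group with six markers) and
reports their joint LR against the no-QTL null. `results.tsv` holds the positions, LR, the 16 effect estimates and
the residual variance. Then

```sh
epiqtl permute --map fam/map.tsv --geno fam/genotypes.tsv \
               --pheno fam/phenotypes.tsv --groups LG1,LG1 --step 2 \
               --n-perm 1000 --alpha 0.05 --seed 17 --out results.tsv
epiqtl effects --map fam/map.tsv --geno fam/genotypes.tsv \
               --pheno fam/phenotypes.tsv --pos1 LG1:30 --pos2 LG1:70 \
               --out effects.tsv
```

add the permutation threshold and the 15 per-effect likelihood-ratio
tests. The same pipeline runs from Python via
`epiqtl.simulate_family`, `epiqtl.scan_pair`,
`epiqtl.permutation_threshold` and `epiqtl.effect_tests`.

Input formats are plain TSV: a linkage map (`group, marker,
position_cM`), offspring genotypes (`id` plus one `13/14/23/24` code per
marker) and phenotypes (`id, value`); see `docs/methods.md` for details
and modelling choices.

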