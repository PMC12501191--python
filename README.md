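# tpsevo

Tools for tracing the functional evolution of enzymes along a phylogeny,
built around the study design used for conifer diterpene synthases (the
TPS-d3 subfamily): reconstruct ancestral protein sequences, engineer
alternative ancestors, point mutants and region-swap chimeras in silico,
turn replicate assay peak tables into product profiles, place enzymes in a
low-dimensional "functional space", and quantify how much a substitution's
effect depends on its genetic background (epistasis).

## What it computes

**Ancestral reconstruction.** Felsenstein's pruning algorithm on a rooted
binary tree under an empirical amino-acid model (JTT, or Poisson) with K
discrete-gamma rate categories. The rate matrix is `Q_ij = S_ij π_j`
(normalised to one expected substitution/site); marginal empirical-Bayes
posteriors `P(state at node v | all tip data)` are computed per site by
combining inside (subtree) and outside (rest-of-tree) partial likelihoods,
integrating over rate categories with likelihood-proportional weights.
The maximum-posterior sequence is emitted per node, and *AltAll*-style
alternative ancestors substitute the second-best residue wherever its
posterior exceeds a threshold (default 0.2), optionally restricted to a
region mask (*AltAlpha*).

**Product profiling.** Long-format peak tables (enzyme, replicate,
analyte, area) become per-replicate compositions (`area / trace total`),
replicate mean ± SD profiles with activity flags (a replicate below 0.1%
of the internal standard is inactive), and log10 total-activity measures.

**Functional space.** Bray–Curtis dissimilarity `Σ|p−q| / Σ(p+q)` over a
name-union product vocabulary; the *functional distance* of a variant from
its ancestor is Bray–Curtis(variant, ancestor) normalised by
Bray–Curtis(pure-isopimaradiene reference, ancestor). Nonmetric MDS
minimises Kruskal stress-1 `sqrt(Σ(d−d̂)²/Σd²)` by alternating
pool-adjacent-violators monotone regression with Guttman-transform
updates, best of 20 seeded starts.

**Epistasis.** A mutation's effect in a background is its composition
shift Δ = mutant − background; the divergence of the same mutation across
two backgrounds is `0.5 Σ|Δ₁−Δ₂| ∈ [0, 2]` (0 iff identical effects).
Loss-of-function mutants are a separate category — flagged, excluded from
divergence with an explicit marker, and checked for rescue by second
mutations. Trajectories track a mutation's focal-product gain along an
ordered ancestor path, with the x-axis scaled to cumulative alpha-domain
Hamming distances and per-interval fold changes.

**Synthetic data.** A generator producing trees, evolved alignments with
recorded ancestral states, a rule-based genotype→product map with planted
background-dependent mutations (and an additive control), Dirichlet +
lognormal replicate assay noise, and a full study bundle with a
ground-truth manifest.

## Worked example

```
$ tpsevo simulate --seed 42 --out bundle
wrote synthetic study (seed 42) to bundle
$ tpsevo profile --peaks bundle/peaks.csv --out profiles.tsv
45 profiles (6 inactive) -> profiles.tsv
$ tpsevo distance --profiles profiles.tsv --out distances.tsv
39 x 39 distance matrix -> distances.tsv
$ tpsevo nmds --distances distances.tsv --seed 0 --out-prefix space
stress 0.0251 (best of 20 starts)
$ tpsevo trajectory --ancestors bundle/ancestors.fasta \
    --profiles profiles.tsv --mutant-suffix 1 --mask 550-850 --out traj.tsv
Anc1 -> Anc2: 0.90-fold
Anc2 -> Anc3: 0.79-fold
Anc3 -> Anc4: 1.39-fold
Anc4 -> Anc5: 1.76-fold
Anc5 -> Anc6: 3.17-fold
```

The bundle contains six path ancestors, their point mutants (e.g. `M4-1` =
A723T in the Anc4 background) and chimeras, and noisy triplicate peak
tables. Six enzymes are inactive (the conditionally lethal 833 mutants)
and are excluded from the 39-enzyme functional space, which embeds in
three dimensions with Kruskal stress 0.025. The trajectory output tracks
how much isopimaradiene the A723T mutant makes in each successive
background: the fold changes hover around 1 across the three basal-class
intervals (cumulative 113 alpha-domain substitutions) and then jump at the
background-class switches (1.76-fold at the Anc4→Anc5 interval of 10
substitutions, 3.17-fold at Anc5→Anc6) — the planted background
dependence, recovered from noisy replicates.

The same steps run in Python via `tpsevo.make_study`,
`tpsevo.profiles_from_table`, `tpsevo.distance_matrix`, `tpsevo.nmds`,
`tpsevo.iso_trajectory` and `tpsevo.fold_changes`; ancestral
reconstruction via `tpsevo.PhyloInstance`, `tpsevo.SubstitutionModel.jtt`
and `tpsevo.marginal_posteriors` (CLI: `tpsevo asr`).

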