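"""Synthetic data: trees, evolving sequences, genotype->product rules, assays.

Generates complete parameterised datasets with known ground truth so every
pipeline stage is testable without downloads:

* random rooted binary trees and amino-acid alignments evolved under a
  substitution model with discrete-gamma rates, recording the true states
  at every internal node (ground truth for reconstruction recovery);
* a rule-based genotype->product-composition map over a small diterpene
  vocabulary with planted pairwise epistasis among three determinant
  sites (a 723-like specificity switch whose effectiveness is gated by
  background-class "context" sites, a 724-like mixed-pimarane switch, a
  conditionally lethal 833-like substitution rescued by 724) plus an
  additive control mutation whose effect is background-independent;
* noisy replicate assay tables: Dirichlet compositional scatter around the
  true composition, lognormal trace-to-trace total-area variation, a
  constant internal standard, and a detection threshold;
* a full study bundle (ancestor path with scripted substitution intervals,
  point mutants and chimeras in every background, replicate peak tables,
  and a ground-truth manifest).

The map is rule-based, not mechanistic: it reproduces the qualitative
structure of real determinant-site behaviour, and the default base
compositions are round-number stand-ins, never measurements.  Every
generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .ancestral import ALPHABET, N_STATES, SubstitutionModel
from .errors import InputError
from .profiling import (DEFAULT_VOCABULARY, INTERNAL_STANDARD, PeakTable,
                        ProductProfile)
from .variants import (PointEdit, ReferenceNumbering, RegionSet, VariantSpec,
                       apply_variant)

LEVO = "levopimaradiene"
ABIET = "abietadiene"
OHABI = "13-OH-abietene"
ISO = "isopimaradiene"
SAN = "sandaracopimaradiene"
ISO815 = "isopimara-8,15-diene"
PIM = "pimaradiene"
PIM911 = "pimara-9(11),15-diene"


# ---------------------------------------------------------------------------
# Trees and sequence evolution
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, branch_range: tuple = (0.05, 0.2),
                  seed: int = 0) -> dendropy.Tree:
    """Random rooted binary tree with uniform branch lengths.

    Tips are t1..tn; internal nodes are labeled node1.. in construction
    order (the root is node1).  Deterministic given the seed.
    """
    if n_tips < 2:
        raise InputError(f"n_tips must be >= 2, got {n_tips}")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    rng.shuffle(labels)
    counter = [0]

    def build(labs):
        if len(labs) == 1:
            return labs[0]
        counter[0] += 1
        me = f"node{counter[0]}"
        k = int(rng.integers(1, len(labs)))
        bl1, bl2 = rng.uniform(*branch_range, size=2)
        left, right = build(labs[:k]), build(labs[k:])
        return f"({left}:{bl1:.6f},{right}:{bl2:.6f}){me}"

    newick = build(labels) + ";"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


@dataclass
class SimulatedAlignment:
    """Evolved tip alignment plus the true sequences at internal nodes."""

    alignment: dict         # tip label -> sequence
    ancestors: dict         # internal node label -> true sequence
    site_categories: np.ndarray


def _evolve_states(parent_states: np.ndarray, cats: np.ndarray,
                   model: SubstitutionModel, branch_length: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample child states site-wise given parent states and rate categories."""
    child = np.empty_like(parent_states)
    for k, rate in enumerate(model.category_rates):
        idx = np.flatnonzero(cats == k)
        if idx.size == 0:
            continue
        P = model.transition_matrix(rate * branch_length)
        cum = P.cumsum(axis=1)
        u = rng.random(idx.size)
        child[idx] = (u[:, None] > cum[parent_states[idx]]).sum(axis=1)
    return np.clip(child, 0, N_STATES - 1)


def simulate_alignment(tree: dendropy.Tree, model: SubstitutionModel, L: int,
                       seed: int = 0) -> SimulatedAlignment:
    """Evolve sequences over a tree, recording every internal node's states.

    The root sequence is drawn from the model's equilibrium frequencies;
    each site carries one gamma rate category for the whole tree.
    """
    rng = np.random.default_rng(seed)
    cats = rng.integers(0, model.K, size=L)
    states = {tree.seed_node: rng.choice(N_STATES, size=L, p=model.pi)}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            bl = node.edge.length or 0.0
            states[node] = _evolve_states(states[node.parent_node], cats,
                                          model, bl, rng)
    to_seq = np.array(list(ALPHABET))
    alignment, ancestors = {}, {}
    counter = 0
    for node in tree.preorder_node_iter():
        seq = "".join(to_seq[states[node]])
        if node.is_leaf():
            alignment[node.taxon.label] = seq
        else:
            if not node.label:
                counter += 1
                node.label = f"node{counter}"
            ancestors[node.label] = seq
    return SimulatedAlignment(alignment, ancestors, cats)


# ---------------------------------------------------------------------------
# Genotype -> phenotype rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """One ordered rule: residue predicate (+ optional context class) -> outcome."""

    name: str
    conditions: dict       # reference position -> allowed residues
    outcome: dict | None   # base composition, or None for inactive
    context: str | None = None

    def matches(self, residue_at, context_class: str) -> bool:
        if self.context is not None and self.context != context_class:
            return False
        return all(residue_at(pos) in allowed
                   for pos, allowed in self.conditions.items())


@dataclass(frozen=True)
class RuleTable:
    """Ordered genotype->composition rules with background-class gating.

    ``context_classes`` is an ordered mapping label -> residue conditions on
    the context sites; the first matching label is the sequence's class,
    with ``default_class`` as catch-all.  Rules are evaluated in order and
    the first match wins; ``default_rules`` (by class) catch everything
    else, so the table is total.
    """

    determinant_sites: tuple
    context_sites: tuple
    context_classes: tuple   # ((label, {pos: frozenset(residues)}), ...)
    rules: tuple             # ordered Rule instances
    class_defaults: dict     # class label -> base composition
    default_class: str = "basal"

    def __post_init__(self):
        for rule in self.rules:
            if rule.outcome is not None:
                s = sum(rule.outcome.values())
                if not np.isclose(s, 1.0, atol=1e-9):
                    raise InputError(f"rule {rule.name!r} composition sums to {s}")
        for label, comp in self.class_defaults.items():
            if not np.isclose(sum(comp.values()), 1.0, atol=1e-9):
                raise InputError(f"default composition for class {label!r} "
                                 "does not sum to 1")

    def classify(self, sequence: str,
                 numbering: ReferenceNumbering | None = None) -> str:
        res = _residue_getter(sequence, numbering)
        for label, conditions in self.context_classes:
            if all(res(pos) in allowed for pos, allowed in conditions.items()):
                return label
        return self.default_class


def _residue_getter(sequence: str, numbering: ReferenceNumbering | None):
    def res(pos: int) -> str:
        i = numbering.to_column(pos) - 1 if numbering is not None else pos - 1
        if not 0 <= i < len(sequence):
            raise InputError(f"sequence does not cover reference position {pos}")
        return sequence[i]
    return res


def phenotype_from_genotype(sequence: str, rules: RuleTable,
                            numbering: ReferenceNumbering | None = None):
    """Base product composition (or None = inactive) for a sequence.

    Ordered semantics: the first matching rule wins; the per-class default
    composition catches all remaining genotypes.
    """
    res = _residue_getter(sequence, numbering)
    cls = rules.classify(sequence, numbering)
    for rule in rules.rules:
        if rule.matches(res, cls):
            return dict(rule.outcome) if rule.outcome is not None else None
    return dict(rules.class_defaults[cls])


# Default planted system ----------------------------------------------------

#: Determinant sites of the default rule table.
SITE_SWITCH, SITE_NEIGHBOR, SITE_LETHAL = 723, 724, 833
#: Additive control mutation site.
SITE_CONTROL = 700
#: Context ("background class") sites, inside the alpha-domain mask.
CONTEXT_SITES = (560, 561)

ISO_DOMINANT = {ISO: 0.9, SAN: 0.1}
ABIETANE_BG = {OHABI: 0.8, ABIET: 0.15, LEVO: 0.05}
LEVO_BG = {LEVO: 0.8, ABIET: 0.15, OHABI: 0.05}


def default_rules() -> RuleTable:
    """The bundled planted system around sites 723/724/833.

    Encodes: a conditionally lethal 833 substitution rescued by the 724
    substitution (sign-changing context dependence); a 724 switch toward
    mixed pimaranes; a 723 specificity switch whose effectiveness is gated
    by the background class (weak in the basal class, ~2x stronger after
    the first context change, dominant in the derived class); and an
    additive control at site 700 whose compositional shift is identical in
    every class.
    """
    S, N, Lt = SITE_SWITCH, SITE_NEIGHBOR, SITE_LETHAL
    rules = (
        Rule("833-lethal-without-724", {Lt: frozenset("Y"), N: frozenset("L")}, None),
        Rule("833+724-rescue-derived", {Lt: frozenset("Y"), N: frozenset("G")},
             dict(ISO_DOMINANT), context="genus"),
        Rule("833+724-rescue-ancestral", {Lt: frozenset("Y"), N: frozenset("G")},
             {OHABI: 0.75, LEVO: 0.10, ABIET: 0.08, ISO: 0.07}),
        Rule("724-mixed-pimaranes-derived", {N: frozenset("G")},
             {ISO: 0.45, SAN: 0.34, ISO815: 0.21}, context="genus"),
        Rule("724-sandaraco-ancestral", {N: frozenset("G")},
             {SAN: 0.8, OHABI: 0.1, ABIET: 0.1}),
        Rule("723T-derived", {S: frozenset("T")}, dict(ISO_DOMINANT), context="genus"),
        Rule("723S-derived", {S: frozenset("S")}, dict(ISO_DOMINANT), context="genus"),
        Rule("723T-intermediate", {S: frozenset("T")},
             {ISO: 0.30, SAN: 0.50, PIM911: 0.15, LEVO: 0.05}, context="pinaceae"),
        Rule("723S-intermediate", {S: frozenset("S")},
             {ISO: 0.18, SAN: 0.57, PIM911: 0.20, LEVO: 0.05}, context="pinaceae"),
        Rule("723T-basal", {S: frozenset("T")},
             {ISO: 0.15, SAN: 0.55, PIM911: 0.25, LEVO: 0.05}),
        Rule("723S-basal", {S: frozenset("S")},
             {ISO: 0.10, SAN: 0.60, PIM911: 0.25, LEVO: 0.05}),
        # additive control: shifts 0.15 from abietadiene to pimaradiene in
        # every class (identical delta vector -> zero true divergence)
        Rule("control-additive-basal", {SITE_CONTROL: frozenset("V")},
             {LEVO: 0.8, OHABI: 0.05, PIM: 0.15}, context="basal"),
        Rule("control-additive-pinaceae", {SITE_CONTROL: frozenset("V")},
             {OHABI: 0.8, LEVO: 0.05, PIM: 0.15}, context="pinaceae"),
        Rule("control-additive-genus", {SITE_CONTROL: frozenset("V")},
             {OHABI: 0.8, LEVO: 0.05, PIM: 0.15}, context="genus"),
    )
    return RuleTable(
        determinant_sites=(S, N, Lt),
        context_sites=CONTEXT_SITES,
        context_classes=(
            ("genus", {CONTEXT_SITES[0]: frozenset("Q"),
                       CONTEXT_SITES[1]: frozenset("N")}),
            ("pinaceae", {CONTEXT_SITES[0]: frozenset("Q")}),
        ),
        rules=rules,
        class_defaults={"basal": dict(LEVO_BG), "pinaceae": dict(ABIETANE_BG),
                        "genus": dict(ABIETANE_BG)},
        default_class="basal",
    )


#: Residues each background class carries at the context sites.
CLASS_RESIDUES = {
    "basal": {CONTEXT_SITES[0]: "E", CONTEXT_SITES[1]: "D"},
    "pinaceae": {CONTEXT_SITES[0]: "Q", CONTEXT_SITES[1]: "D"},
    "genus": {CONTEXT_SITES[0]: "Q", CONTEXT_SITES[1]: "N"},
}

#: Residues every simulated ancestor carries at the scripted sites.
ANCESTRAL_RESIDUES = {SITE_SWITCH: "A", SITE_NEIGHBOR: "L",
                      SITE_LETHAL: "N", SITE_CONTROL: "A"}


# ---------------------------------------------------------------------------
# Assay noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayNoiseModel:
    """Replicate assay noise: compositional scatter and peak-area scaling.

    kappa: Dirichlet concentration (replicate composition ~ Dirichlet(kappa *
    base) over the base's support); sigma: lognormal spread of the total
    analyte area; areas in arbitrary integrator units.
    """

    kappa: float = 200.0
    sigma: float = 0.3
    internal_standard_area: float = 1.0e6
    mean_total_area: float = 1.0e5
    detection_fraction: float = 1e-3

    def __post_init__(self):
        if self.kappa <= 0:
            raise InputError("kappa must be > 0")
        if self.sigma < 0:
            raise InputError("sigma must be >= 0")


def _assay_rows(base: dict | None, enzyme: str, n_replicates: int,
                noise: AssayNoiseModel, rng: np.random.Generator,
                vocabulary=DEFAULT_VOCABULARY) -> list:
    rows = []
    base = base or {}
    support = [p for p in vocabulary if base.get(p, 0.0) > 0]
    alphas = np.array([base[p] for p in support]) * noise.kappa
    for r in range(1, n_replicates + 1):
        rep = f"r{r}"
        if support:
            comp = rng.dirichlet(alphas)
            total = noise.mean_total_area * np.exp(noise.sigma * rng.standard_normal())
            areas = dict(zip(support, comp * total))
        else:
            areas = {}
        for p in vocabulary:
            rows.append({"enzyme": enzyme, "replicate": rep, "analyte": p,
                         "area": areas.get(p, 0.0)})
        rows.append({"enzyme": enzyme, "replicate": rep,
                     "analyte": INTERNAL_STANDARD,
                     "area": noise.internal_standard_area})
    return rows


def simulate_assays(base: dict | None, n_replicates: int = 3,
                    noise: AssayNoiseModel = AssayNoiseModel(),
                    seed: int = 0, enzyme: str = "enzyme",
                    vocabulary=DEFAULT_VOCABULARY) -> PeakTable:
    """Noisy replicate peak table for one enzyme.

    Active enzymes get Dirichlet-scattered compositions scaled by a
    lognormal total area; an inactive ``base`` (None) yields all-zero
    analyte areas.  The internal standard is constant.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = _assay_rows(base, enzyme, n_replicates, noise, rng, vocabulary)
    return PeakTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Design of the default synthetic study.

    Six ancestors on a path; masked alpha-domain substitution intervals
    (40, 40, 33, 10, 20) so the cumulative distance reaches 113 before the
    first context change and the two derived intervals span 10 and 20
    substitutions; the background class switches from basal to an
    intermediate class on the 4th->5th interval and to the derived class on
    the 5th->6th.  Each background receives the 723T/723S switch mutants,
    the 724/833 single and double mutants, and the additive control; the
    last backbone pair additionally receives region-swap chimeras.
    """

    n_ancestors: int = 6
    intervals: tuple = (40, 40, 33, 10, 20)
    L: int = 850
    alpha_domain: tuple = (550, 850)
    class_path: tuple = ("basal", "basal", "basal", "basal", "pinaceae", "genus")
    mutation_sets: tuple = (
        ("1", ("A723T",)),
        ("2", ("A723S",)),
        ("3", ("L724G",)),
        ("4", ("N833Y",)),
        ("5", ("L724G", "N833Y")),
        ("6", ("A700V",)),
    )
    regions: tuple = (("X", ((550, 650),)), ("Y", ((651, 750),)),
                      ("Z", ((751, 850),)))
    n_replicates: int = 3
    noise: AssayNoiseModel = field(default_factory=AssayNoiseModel)
    tip_branch_length: float = 0.02
    alpha: float = 1.0
    K: int = 4

    def __post_init__(self):
        if len(self.intervals) != self.n_ancestors - 1:
            raise InputError("need one interval per consecutive ancestor pair")
        if len(self.class_path) != self.n_ancestors:
            raise InputError("class_path must name one class per ancestor")

    @property
    def alpha_mask(self) -> frozenset:
        return frozenset(range(self.alpha_domain[0], self.alpha_domain[1] + 1))


@dataclass
class StudyBundle:
    """A complete synthetic dataset plus its ground-truth manifest."""

    config: StudyConfig
    seed: int
    newick: str
    tip_alignment: dict
    ancestors: dict            # ancestor id -> sequence (ordered along the path)
    variant_specs: list
    variant_sequences: dict    # code -> sequence
    peak_table: PeakTable
    rules: RuleTable
    regions: RegionSet
    numbering: ReferenceNumbering
    manifest: dict

    def write(self, outdir) -> None:
        """Write the bundle as plain-text files (Newick/FASTA/CSV/JSON)."""
        import os
        os.makedirs(outdir, exist_ok=True)
        join = lambda name: os.path.join(str(outdir), name)
        with open(join("tree.nwk"), "w") as fh:
            fh.write(self.newick + "\n")
        _write_fasta(join("tips.fasta"), self.tip_alignment)
        _write_fasta(join("ancestors.fasta"), self.ancestors)
        _write_fasta(join("variants.fasta"), self.variant_sequences)
        with open(join("variants.json"), "w") as fh:
            json.dump([{"code": v.code, "background": v.background,
                        "edits": ";".join(str(e) for e in v.edits),
                        "swaps": ";".join(f"{r}:{d}" for r, d in v.swaps)}
                       for v in self.variant_specs], fh, indent=1, sort_keys=True)
        with open(join("regions.json"), "w") as fh:
            json.dump({k: [list(iv) for iv in v]
                       for k, v in self.regions.regions.items()},
                      fh, indent=1, sort_keys=True)
        self.peak_table.data.to_csv(join("peaks.csv"), index=False)
        with open(join("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def _write_fasta(path, seqs: dict) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def _random_sequence(rng, model: SubstitutionModel, L: int) -> list:
    states = rng.choice(N_STATES, size=L, p=model.pi)
    return [ALPHABET[i] for i in states]


def make_study(config: StudyConfig | None = None, seed: int = 0) -> StudyBundle:
    """Generate the full synthetic study: the end-to-end pipeline fixture."""
    cfg = config or StudyConfig()
    rules = default_rules()
    model = SubstitutionModel.jtt(alpha=cfg.alpha, K=cfg.K)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    numbering = ReferenceNumbering.identity(cfg.L)

    scripted = set(ANCESTRAL_RESIDUES) | set(CONTEXT_SITES)
    # --- ancestor path with exact masked substitution intervals
    anc_ids = [f"Anc{i + 1}" for i in range(cfg.n_ancestors)]
    first = _random_sequence(rng, model, cfg.L)
    for pos, res in ANCESTRAL_RESIDUES.items():
        first[pos - 1] = res
    for pos, res in CLASS_RESIDUES[cfg.class_path[0]].items():
        first[pos - 1] = res
    sequences = {anc_ids[0]: "".join(first)}

    free_sites = sorted(cfg.alpha_mask - scripted)
    scripted_changes = []
    for i in range(1, cfg.n_ancestors):
        prev_cls, cls = cfg.class_path[i - 1], cfg.class_path[i]
        changes = {pos: CLASS_RESIDUES[cls][pos] for pos in CONTEXT_SITES
                   if CLASS_RESIDUES[cls][pos] != CLASS_RESIDUES[prev_cls][pos]}
        scripted_changes.append(changes)
        if len(changes) > cfg.intervals[i - 1]:
            raise InputError("interval too small for the scripted class change")
    n_random = [cfg.intervals[i] - len(scripted_changes[i])
                for i in range(cfg.n_ancestors - 1)]
    if sum(n_random) > len(free_sites):
        raise InputError("alpha domain too small for the requested intervals")
    chosen = rng.choice(len(free_sites), size=sum(n_random), replace=False)
    chosen_iter = iter(chosen)

    for i in range(1, cfg.n_ancestors):
        seq = list(sequences[anc_ids[i - 1]])
        for pos, res in scripted_changes[i - 1].items():
            seq[pos - 1] = res
        for _ in range(n_random[i - 1]):
            pos = free_sites[next(chosen_iter)]
            current = seq[pos - 1]
            alternatives = [a for a in ALPHABET if a != current]
            seq[pos - 1] = alternatives[int(rng.integers(len(alternatives)))]
        sequences[anc_ids[i]] = "".join(seq)

    # --- backbone tree with one evolved tip per ancestor
    mask_size = len(cfg.alpha_mask)
    tip_alignment = {}
    for anc in anc_ids:
        parent = np.array([ALPHABET.index(c) for c in sequences[anc]])
        cats = rng.integers(0, model.K, size=cfg.L)
        tip = _evolve_states(parent, cats, model, cfg.tip_branch_length, rng)
        tip_alignment[f"{anc}_tip"] = "".join(ALPHABET[s] for s in tip)
    parent = np.array([ALPHABET.index(c) for c in sequences[anc_ids[-1]]])
    cats = rng.integers(0, model.K, size=cfg.L)
    extra = _evolve_states(parent, cats, model, cfg.tip_branch_length, rng)
    tip_alignment[f"{anc_ids[-1]}_tip2"] = "".join(ALPHABET[s] for s in extra)

    tb = cfg.tip_branch_length
    newick = f"({anc_ids[-1]}_tip:{tb:.6f},{anc_ids[-1]}_tip2:{tb:.6f}){anc_ids[-1]}"
    for i in range(cfg.n_ancestors - 2, -1, -1):
        bl = cfg.intervals[i] / mask_size
        newick = f"({anc_ids[i]}_tip:{tb:.6f},{newick}:{bl:.6f}){anc_ids[i]}"
    newick += ";"

    # --- variants: point mutants in every background, chimeras on the last pair
    regions = RegionSet(dict((n, list(iv)) for n, iv in cfg.regions))
    specs = []
    for i, anc in enumerate(anc_ids):
        for suffix, edits in cfg.mutation_sets:
            specs.append(VariantSpec(code=f"M{i + 1}-{suffix}", background=anc,
                                     edits=tuple(PointEdit.parse(e) for e in edits)))
    donor_idx = cfg.n_ancestors  # e.g. "M5-7": Anc5 background, Anc6 donor
    recipient = anc_ids[-2]
    for j, sel in enumerate((("X",), ("Y",), ("X", "Y", "Z"))):
        specs.append(VariantSpec(code=f"M{cfg.n_ancestors - 1}-{7 + j}",
                                 background=recipient,
                                 swaps=tuple((r, anc_ids[-1]) for r in sel)))

    variant_sequences = {
        spec.code: apply_variant(spec, sequences, regions, numbering)
        for spec in specs
    }

    # --- true compositions and noisy assays
    vocabulary = DEFAULT_VOCABULARY
    true_comps = {}
    for name, seq in {**sequences, **variant_sequences}.items():
        true_comps[name] = phenotype_from_genotype(seq, rules, numbering)
    rows = []
    for name in list(sequences) + list(variant_sequences):
        rows.extend(_assay_rows(true_comps[name], name, cfg.n_replicates,
                                cfg.noise, rng, vocabulary))
    peak_table = PeakTable(pd.DataFrame(rows))

    # --- ground-truth manifest
    cumulative = np.concatenate([[0], np.cumsum(cfg.intervals)]).tolist()
    trajectories = {}
    for suffix in ("1", "2"):
        pts = []
        for i, anc in enumerate(anc_ids):
            comp = true_comps[f"M{i + 1}-{suffix}"]
            pts.append({"ancestor": anc, "x": cumulative[i],
                        "true_focal": None if comp is None else comp.get(ISO, 0.0)})
        trajectories[suffix] = pts
    planted_pair = [anc_ids[3], anc_ids[4]]  # straddles the first class switch
    planted_div = _true_divergence(true_comps, "M4-1", "M5-1",
                                   anc_ids[3], anc_ids[4])
    control_div = _true_divergence(true_comps, "M4-6", "M5-6",
                                   anc_ids[3], anc_ids[4])
    manifest = {
        "seed": seed,
        "ancestors": anc_ids,
        "classes": list(cfg.class_path),
        "intervals": list(cfg.intervals),
        "cumulative_x": cumulative,
        "alpha_domain": list(cfg.alpha_domain),
        "true_compositions": true_comps,
        "trajectories": trajectories,
        "planted": {
            "mutation": "A723T", "codes": ["M4-1", "M5-1"],
            "backgrounds": planted_pair, "true_divergence": planted_div,
            "control_mutation": "A700V", "control_codes": ["M4-6", "M5-6"],
            "control_true_divergence": control_div,
        },
    }
    return StudyBundle(cfg, seed, newick, tip_alignment, sequences, specs,
                       variant_sequences, peak_table, rules, regions,
                       numbering, manifest)


def _true_profile(comp: dict | None, enzyme: str) -> ProductProfile:
    if comp is None:
        return ProductProfile(enzyme, (), np.array([]), np.array([]), n=0,
                              active=False, under_replicated=True)
    vocab = tuple(comp)
    mean = np.array([comp[p] for p in vocab])
    return ProductProfile(enzyme, vocab, mean / mean.sum(),
                          np.zeros(len(vocab)), n=1, active=True)


def _true_divergence(true_comps, code_a, code_b, bg_a, bg_b) -> float:
    from .epistasis import effect_divergence, mutation_effect
    e1 = mutation_effect(_true_profile(true_comps[bg_a], bg_a),
                         _true_profile(true_comps[code_a], code_a), code="m")
    e2 = mutation_effect(_true_profile(true_comps[bg_b], bg_b),
                         _true_profile(true_comps[code_b], code_b), code="m")
    return effect_divergence(e1, e2)


# ---------------------------------------------------------------------------
# Planted-epistasis recovery experiment
# ---------------------------------------------------------------------------

@dataclass
class EpistasisExperiment:
    """Outcome of the planted background-dependence recovery experiment."""

    success_rate: float
    n_replicates: int
    planted_divergences: np.ndarray
    control_divergences: np.ndarray


def planted_epistasis_experiment(n_replicates: int = 200,
                                 noise: AssayNoiseModel = AssayNoiseModel(),
                                 n_assay: int = 3,
                                 seed: int = 0) -> EpistasisExperiment:
    """Does the planted background-dependent mutation outrank the control?

    In each replicate, the 723 switch mutation (background-dependent by
    construction) and the additive control are assayed with replicate noise
    in two backgrounds straddling the first context change; success means
    the planted mutation's effect divergence exceeds the control's.
    """
    from .epistasis import effect_divergence, mutation_effect
    from .profiling import profiles_from_table

    rules = default_rules()
    L = 850
    numbering = ReferenceNumbering.identity(L)

    def background_seq(cls: str) -> str:
        seq = ["A"] * L
        for pos, res in ANCESTRAL_RESIDUES.items():
            seq[pos - 1] = res
        for pos, res in CLASS_RESIDUES[cls].items():
            seq[pos - 1] = res
        return "".join(seq)

    enzymes = {}
    for cls, tag in (("basal", "B1"), ("pinaceae", "B2")):
        bg = background_seq(cls)
        enzymes[tag] = bg
        mut = list(bg); mut[SITE_SWITCH - 1] = "T"
        enzymes[f"{tag}_planted"] = "".join(mut)
        ctl = list(bg); ctl[SITE_CONTROL - 1] = "V"
        enzymes[f"{tag}_control"] = "".join(ctl)
    comps = {name: phenotype_from_genotype(seq, rules, numbering)
             for name, seq in enzymes.items()}

    ss = np.random.SeedSequence(seed)
    planted, control = [], []
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        rows = []
        for name in enzymes:
            rows.extend(_assay_rows(comps[name], name, n_assay, noise, rng))
        profiles = profiles_from_table(
            PeakTable(pd.DataFrame(rows)),
            detection_fraction=noise.detection_fraction)
        eff = {}
        for tag in ("B1", "B2"):
            for kind in ("planted", "control"):
                eff[(tag, kind)] = mutation_effect(
                    profiles[tag], profiles[f"{tag}_{kind}"], code=kind)
        planted.append(effect_divergence(eff[("B1", "planted")],
                                         eff[("B2", "planted")]))
        control.append(effect_divergence(eff[("B1", "control")],
                                         eff[("B2", "control")]))
    planted = np.asarray(planted)
    control = np.asarray(control)
    return EpistasisExperiment(
        success_rate=float(np.mean(planted > control)),
        n_replicates=n_replicates,
        planted_divergences=planted, control_divergences=control)
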