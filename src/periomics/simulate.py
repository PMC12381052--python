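"""Synthetic two-group biofilm cohorts with recorded ground truth.

The generator emulates the statistical structure the analysis assumes for
a peri-implant biofilm study: patient-structured paired sampling (each
patient contributes one healthy and one diseased profile, making
patient-block permutation meaningful), a heavy-tailed log-normal base
community with Dirichlet-multinomial count noise for the DNA (species)
block, and an RNA block built from taxon activities crossed with
taxon-specific EC expression profiles.  Disease signal is planted three
ways: multiplicative log-fold effects on chosen species, group-specific
multipliers on amino-acid pathway ECs, and taxon-role plants that scale a
taxon's expression of one pathway relative to its overall activity.  The
realised plants are returned as a :class:`SyntheticTruth` so recovery can
be scored exactly.

Default sizes mirror a desk-scale version of a 24 + 24 sample cohort;
read depths are scaled down from sequencing reality (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from periomics.ec import EcTaxonTensor
from periomics.pathways import PathwayDefinition
from periomics.tables import FeatureTable, SampleMetadata

HEALTH = "healthy"
DISEASE = "peri-implantitis"

AMINO_ACIDS = (
    "histidine", "lysine", "tryptophan", "methionine", "arginine",
    "threonine", "tyrosine", "phenylalanine", "cysteine", "leucine-group",
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``n_patients`` patients each contribute one healthy and one diseased
    sample.  ``effect_species`` species receive a ``2**effect_log2fold``
    multiplicative shift in diseased samples (half up, half down);
    ``pathway_shifts`` maps pathway ids to a disease-side multiplier
    applied to every EC of the pathway; ``role_plants`` scales a taxon's
    expression of one pathway by ``2**role_log2fold`` (sign per role).
    ``overdispersion`` is the Dirichlet concentration scale (larger =
    closer to multinomial).
    """

    n_patients: int = 24
    n_species: int = 150
    n_ecs_per_pathway: int = 5
    n_extra_ecs: int = 100
    housekeeping_scale: float = 4.0
    n_taxa: int = 12
    dna_depth: int = 15_000
    rna_depth: int = 200_000
    effect_species: int = 10
    effect_log2fold: float = 2.0
    pathway_shifts: dict[str, float] = field(default_factory=lambda: {
        # utilisation of these amino acids rises in disease ...
        "histidine_catabolic": 4.0, "lysine_catabolic": 4.0,
        "tryptophan_catabolic": 4.0, "cysteine_catabolic": 4.0,
        # ... while biosynthesis dominates in health
        "methionine_anabolic": 0.25, "arginine_anabolic": 0.25,
        "threonine_anabolic": 0.25, "phenylalanine_anabolic": 0.25,
    })
    role_plants: tuple[tuple[str, str, str], ...] = (
        ("taxon01", "lysine", "high-catabolism"),
        ("taxon02", "histidine", "high-anabolism"),
        ("taxon03", "methionine", "low-anabolism"),
        ("taxon04", "tryptophan", "high-catabolism"),
    )
    role_log2fold: float = 2.5
    sigma_species: float = 1.5
    sigma_taxon: float = 1.0
    sigma_patient: float = 0.4
    overdispersion: float = 300.0
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Realised planted parameters and expected qualitative outcomes."""

    species_effects: dict[str, float]          # species -> log2 fold (disease/health)
    shifted_ecs: dict[str, str]                # EC -> direction label
    role_edges: list[tuple[str, str, str]]     # (taxon, amino_acid, role)
    config: dict

    def to_json(self, path) -> None:
        payload = {"species_effects": self.species_effects,
                   "shifted_ecs": self.shifted_ecs,
                   "role_edges": [list(e) for e in self.role_edges],
                   "config": self.config}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(species_effects=payload["species_effects"],
                   shifted_ecs=payload["shifted_ecs"],
                   role_edges=[tuple(e) for e in payload["role_edges"]],
                   config=payload["config"])


def default_pathways(cfg: SimulationConfig,
                     rng: np.random.Generator) -> list[PathwayDefinition]:
    """Disjoint anabolic/catabolic pathway definitions over a synthetic EC universe."""
    pathways = []
    counter = 1
    for aa in AMINO_ACIDS:
        for direction in ("anabolic", "catabolic"):
            ecs = []
            for _ in range(cfg.n_ecs_per_pathway):
                ecs.append(f"{rng.integers(1, 7)}.{rng.integers(1, 20)}."
                           f"{rng.integers(1, 30)}.{counter}")
                counter += 1
            pathways.append(PathwayDefinition(
                pathway_id=f"{aa}_{direction}", amino_acid=aa,
                direction=direction, ec_set=tuple(ecs),
                note="synthetic pathway"))
    return pathways


def _dirichlet_multinomial(rng: np.random.Generator, p: np.ndarray,
                           depth: int, theta: float) -> np.ndarray:
    alpha = np.clip(theta * p, 1e-9, None)
    probs = rng.dirichlet(alpha)
    return rng.multinomial(depth, probs)


def _lineage(cfg: SimulationConfig, rng: np.random.Generator,
             species: list[str], taxa: list[str]) -> pd.DataFrame:
    n_genera = max(cfg.n_species // 5, 1)
    genera = [f"genus{i + 1:03d}" for i in range(n_genera)]
    genus_of = rng.integers(0, n_genera, size=cfg.n_species)
    class_of_genus = rng.integers(0, cfg.n_taxa, size=n_genera)
    return pd.DataFrame({
        "genus": [genera[g] for g in genus_of],
        "class": [taxa[class_of_genus[g]] for g in genus_of],
        "rank": "species", "source": "DNA",
    }, index=species)


def simulate_cohort(cfg: SimulationConfig):
    """Generate one synthetic cohort.

    Returns ``(dna, rna_genes, annotations, tensor, pathways, metadata,
    truth)``: a species count table with lineage metadata, a gene-level
    RNA count table with its annotation frame, the ground-truth
    sample x EC x taxon count tensor (its taxon marginal equals the EC
    aggregation of the gene table exactly), the pathway definitions, the
    sample metadata, and the realised :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng(cfg.seed)
    pathways = default_pathways(cfg, rng)
    pw_by_id = {p.pathway_id: p for p in pathways}
    for pid in cfg.pathway_shifts:
        if pid not in pw_by_id:
            raise ValueError(f"pathway_shifts references unknown pathway {pid!r}")

    taxa = [f"taxon{i + 1:02d}" for i in range(cfg.n_taxa)]
    for taxon, aa, role in cfg.role_plants:
        if taxon not in taxa:
            raise ValueError(f"role plant references unknown taxon {taxon!r}")
        if aa not in AMINO_ACIDS:
            raise ValueError(f"role plant references unknown amino acid {aa!r}")

    species = [f"sp{i + 1:03d}" for i in range(cfg.n_species)]
    if cfg.effect_species > cfg.n_species:
        raise ValueError("more effect species than species")

    # --- sample design: one healthy + one diseased sample per patient
    sample_ids, patients, diagnosis = [], [], []
    for p in range(cfg.n_patients):
        for dx in (HEALTH, DISEASE):
            sample_ids.append(f"P{p + 1:02d}_{'H' if dx == HEALTH else 'D'}")
            patients.append(f"P{p + 1:02d}")
            diagnosis.append(dx)
    metadata = SampleMetadata(pd.DataFrame(
        {"patient_id": patients, "diagnosis": diagnosis}, index=sample_ids))
    is_disease = np.array([d == DISEASE for d in diagnosis])

    # --- DNA block -------------------------------------------------------
    base = rng.lognormal(0.0, cfg.sigma_species, cfg.n_species)
    # disease-associated taxa are detectable community members, not
    # log-normal-tail singletons: plant effects on above-median species
    eligible = np.flatnonzero(base >= np.median(base))
    effect_idx = rng.choice(eligible, cfg.effect_species, replace=False)
    lfc = np.zeros(cfg.n_species)
    half = cfg.effect_species // 2
    lfc[effect_idx[:half]] = cfg.effect_log2fold
    lfc[effect_idx[half:]] = -cfg.effect_log2fold
    patient_eff = rng.lognormal(0.0, cfg.sigma_patient,
                                (cfg.n_patients, cfg.n_species))

    dna_counts = np.zeros((len(sample_ids), cfg.n_species), dtype=int)
    for i, sid in enumerate(sample_ids):
        p = i // 2
        expect = base * patient_eff[p] * np.exp2(lfc * is_disease[i])
        expect = expect / expect.sum()
        dna_counts[i] = _dirichlet_multinomial(rng, expect, cfg.dna_depth,
                                               cfg.overdispersion)
    lineage = _lineage(cfg, rng, species, taxa)
    dna = FeatureTable(pd.DataFrame(dna_counts, index=sample_ids,
                                    columns=species),
                       scale="counts", feature_meta=lineage)

    # --- RNA block -------------------------------------------------------
    ec_ids = sorted({e for p in pathways for e in p.ec_set})
    extra = [f"9.{i + 1}.1.1" for i in range(cfg.n_extra_ecs)]  # housekeeping pool
    ec_ids = ec_ids + extra
    e_idx = {e: i for i, e in enumerate(ec_ids)}
    n_ecs = len(ec_ids)

    taxon_base = rng.lognormal(0.0, cfg.sigma_taxon, cfg.n_taxa)
    # sparse taxon x EC expression profile; every EC expressed somewhere
    profile = (rng.random((cfg.n_taxa, n_ecs)) < 0.6) * rng.lognormal(
        0.0, 0.5, (cfg.n_taxa, n_ecs))
    for j in range(n_ecs):
        if profile[:, j].sum() == 0:
            profile[rng.integers(cfg.n_taxa), j] = rng.lognormal(0.0, 0.5)
    # most of a transcriptome is core/housekeeping expression; pathway ECs
    # are a minority share, so pathway shifts barely move the denominator
    profile[:, len(ec_ids) - cfg.n_extra_ecs:] *= cfg.housekeeping_scale

    # role-planted taxa are minor community members (below the log-normal
    # median): a dominant taxon cannot exceed its own biofilm share by much,
    # so specialisation plants are only realisable on low-activity taxa
    for taxon, _aa, _role in cfg.role_plants:
        taxon_base[taxa.index(taxon)] = np.exp(-0.5)

    # Plant roles by solving for the pathway expression that makes the
    # taxon's expected share of the pathway equal 2^(+-phi) times its share
    # of whole-community expression (two fixed-point sweeps suffice since
    # one pathway is a small part of a taxon's total expression).
    role_edges: list[tuple[str, str, str]] = []
    for _ in range(2):
        for taxon, aa, role in cfg.role_plants:
            direction = "catabolic" if role == "high-catabolism" else "anabolic"
            pw = pw_by_id[f"{aa}_{direction}"]
            t = taxa.index(taxon)
            cols = [e_idx[e] for e in pw.ec_set]
            weighted = profile * taxon_base[:, None]
            u = weighted[t].sum() / weighted.sum()
            phi = -cfg.role_log2fold if role == "low-anabolism" else cfg.role_log2fold
            target = float(np.clip(2.0 ** phi * u, 1e-6, 0.9))
            rest = weighted[np.arange(cfg.n_taxa) != t][:, cols].sum()
            p_target = target * rest / (1.0 - target)
            w = profile[t, cols]
            w = w / w.sum() if w.sum() > 0 else np.full(len(cols), 1 / len(cols))
            profile[t, cols] = p_target / taxon_base[t] * w
    for taxon, aa, role in cfg.role_plants:
        role_edges.append((taxon, aa, role))

    shift = np.ones(n_ecs)
    shifted_ecs: dict[str, str] = {}
    for pid, mult in cfg.pathway_shifts.items():
        pw = pw_by_id[pid]
        for e in pw.ec_set:
            shift[e_idx[e]] = mult
            shifted_ecs[e] = DISEASE if mult > 1 else HEALTH

    taxon_patient_eff = rng.lognormal(0.0, cfg.sigma_patient,
                                      (cfg.n_patients, cfg.n_taxa))
    tensor = np.zeros((len(sample_ids), n_ecs, cfg.n_taxa), dtype=int)
    for i, sid in enumerate(sample_ids):
        p = i // 2
        activity = taxon_base * taxon_patient_eff[p]
        expect = profile * activity[:, None]          # taxa x ecs
        if is_disease[i]:
            expect = expect * shift[None, :]
        flat = (expect.T).ravel()                      # (ec, taxon) order
        nz = flat > 0                                  # counts only where a gene exists
        p = flat[nz] / flat[nz].sum()
        draw = np.zeros_like(flat, dtype=int)
        draw[nz] = _dirichlet_multinomial(rng, p, cfg.rna_depth,
                                          cfg.overdispersion * 10)
        tensor[i] = draw.reshape(n_ecs, cfg.n_taxa)
    ec_tensor = EcTaxonTensor(tensor.astype(float), sample_ids, ec_ids, taxa)

    # --- gene-level view: one gene per expressed (taxon, EC) pair --------
    genera_of_taxon = {t: [f"{t}_gA", f"{t}_gB"] for t in taxa}
    gene_ids, gene_ec, gene_class, gene_genus, cols = [], [], [], [], []
    for t, taxon in enumerate(taxa):
        for j, ec in enumerate(ec_ids):
            if profile[t, j] > 0:
                gene_ids.append(f"g_{taxon}_{j:04d}")
                gene_ec.append(ec)
                gene_class.append(taxon)
                gene_genus.append(genera_of_taxon[taxon][int(rng.integers(2))])
                cols.append((j, t))
    gene_counts = np.stack([tensor[:, j, t] for j, t in cols], axis=1)
    rna_genes = FeatureTable(
        pd.DataFrame(gene_counts, index=sample_ids, columns=gene_ids),
        scale="counts",
        feature_meta=pd.DataFrame({"rank": "gene", "source": "RNA"},
                                  index=gene_ids))
    annotations = pd.DataFrame({"ec_codes": gene_ec, "class": gene_class,
                                "genus": gene_genus}, index=gene_ids)
    annotations.index.name = "gene_id"

    truth = SyntheticTruth(
        species_effects={species[i]: float(lfc[i]) for i in effect_idx},
        shifted_ecs=shifted_ecs, role_edges=role_edges,
        config={**asdict(cfg),
                "role_plants": [list(r) for r in cfg.role_plants]},
    )
    return dna, rna_genes, annotations, ec_tensor, pathways, metadata, truth


# ---------------------------------------------------------------------------
# Recovery scoring


def _precision_recall(found: set, planted: set) -> dict:
    tp = len(found & planted)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return {"tp": tp, "found": len(found), "planted": len(planted),
            "precision": precision, "recall": recall}


def truth_check(truth: SyntheticTruth, *, selected_ecs=None,
                selected_species=None, role_edges=None) -> dict:
    """Precision/recall of pipeline outputs against the planted truth.

    Any subset of the three result kinds may be passed; an empty result
    list gives recall 0 and an undefined (nan) precision.
    """
    report: dict[str, dict] = {}
    if selected_ecs is not None:
        report["ecs"] = _precision_recall(set(selected_ecs),
                                          set(truth.shifted_ecs))
    if selected_species is not None:
        report["species"] = _precision_recall(set(selected_species),
                                              set(truth.species_effects))
    if role_edges is not None:
        found = {tuple(e) for e in role_edges}
        report["roles"] = _precision_recall(found, set(truth.role_edges))
    return report
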