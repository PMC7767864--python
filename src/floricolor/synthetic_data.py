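"""Synthetic flower-color study generator.

Emulates the statistical structure of a reflectance + pigment +
phylogeny study of a tropical flower radiation so every pipeline stage
can be exercised without measured data: smooth flower-like reflectance
curves built from logistic steps and Gaussian bands (amplitudes
straddling the 20-pp marker rule), compositional pigment vectors
concentrated in the four chemistry categories, pure-birth ultrametric
trees, and phylogenetically clustered placement of the
deoxyanthocyanin-producing samples (thresholding a latent Brownian
trait), so group comparisons face realistic non-independence.

The default design mirrors a 180-sample study: 24 DEO90, 32 DEO_HYD,
96 HYD90 and 28 anthocyanin-free samples, deoxyanthocyanin flowers
carrying a single steep transition near 600 nm and hydroxyanthocyanin
flowers spanning red, yellow, purple and white spectral shapes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from . import chemistry
from .chemistry import DEO90, DEO_HYD, HYD90, NONE, PigmentComposition
from .phylo import Phylogeny
from .spectra import ReflectanceSpectrum, SpectrumSet, average_replicates, standard_grid

ARCHETYPES = (
    "red_step",
    "white_flat",
    "yellow_step",
    "purple_bimodal",
    "green_leaf",
    "low_flat",
)

#: spectral-shape mixture per pigment category
CATEGORY_ARCHETYPE_WEIGHTS: dict[str, dict[str, float]] = {
    DEO90: {"red_step": 1.0},
    DEO_HYD: {"red_step": 0.8, "purple_bimodal": 0.2},
    HYD90: {
        "red_step": 0.40,
        "yellow_step": 0.25,
        "purple_bimodal": 0.25,
        "white_flat": 0.10,
    },
    NONE: {"white_flat": 0.40, "yellow_step": 0.30, "green_leaf": 0.15, "low_flat": 0.15},
}


def _logistic(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(grid - center) / width))


def make_flower_spectrum(
    archetype: str,
    params: dict | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
    part: str = "whole",
) -> ReflectanceSpectrum:
    """Generate one noisy flower-like reflectance curve.

    Archetypes (params override the drawn defaults):

    * ``red_step`` — <10% below a steep transition near 595-615 nm
      (``center``), >30% above: codes orange/red, one marker ~center;
    * ``yellow_step`` — transition near 500 nm, high beyond;
    * ``white_flat`` — flat high reflectance (``level``, default ~60%);
    * ``purple_bimodal`` — blue band near 440 nm plus a far-red rise;
    * ``green_leaf`` — foliage-like 550-nm band, amplitude below the
      20-pp marker rule;
    * ``low_flat`` — dark, featureless.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    rng = np.random.default_rng(seed) if rng is None else rng
    params = dict(params or {})
    grid = standard_grid()
    noise_sd = params.pop("noise_sd", 0.4)

    if archetype == "red_step":
        center = params.pop("center", rng.uniform(595.0, 615.0))
        width = params.pop("width", rng.uniform(4.0, 8.0))
        amp = params.pop("amplitude", rng.uniform(40.0, 60.0))
        base = params.pop("base", rng.uniform(2.0, 4.0))
        refl = base + amp * _logistic(grid, center, width)
    elif archetype == "yellow_step":
        center = params.pop("center", rng.uniform(490.0, 515.0))
        width = params.pop("width", rng.uniform(5.0, 10.0))
        amp = params.pop("amplitude", rng.uniform(35.0, 55.0))
        base = params.pop("base", rng.uniform(3.0, 6.0))
        refl = base + amp * _logistic(grid, center, width)
    elif archetype == "white_flat":
        level = params.pop("level", rng.uniform(50.0, 70.0))
        refl = np.full_like(grid, level)
    elif archetype == "purple_bimodal":
        band_center = params.pop("band_center", rng.uniform(425.0, 455.0))
        band_amp = params.pop("band_amplitude", rng.uniform(30.0, 45.0))
        band_sd = params.pop("band_sd", rng.uniform(25.0, 35.0))
        red_center = params.pop("red_center", rng.uniform(615.0, 650.0))
        red_amp = params.pop("red_amplitude", rng.uniform(25.0, 45.0))
        base = params.pop("base", rng.uniform(2.0, 5.0))
        refl = (
            base
            + band_amp * np.exp(-0.5 * ((grid - band_center) / band_sd) ** 2)
            + red_amp * _logistic(grid, red_center, 10.0)
        )
    elif archetype == "green_leaf":
        base = params.pop("base", 3.0)
        refl = base + 12.0 * np.exp(-0.5 * ((grid - 550.0) / 40.0) ** 2)
    else:  # low_flat
        level = params.pop("level", rng.uniform(3.0, 6.0))
        refl = np.full_like(grid, level)

    if params:
        raise ValueError(f"unused parameter(s) for {archetype!r}: {sorted(params)}")
    refl = refl + rng.normal(0.0, noise_sd, size=grid.shape)
    return ReflectanceSpectrum(sample_id, part, grid, np.clip(refl, 0.0, None))


_DEOXY_MEMBERS = ("luteolinidin", "apigenidin", "unknown_deoxy")
_HYDROXY_MEMBERS = ("pelargonidin", "cyanidin", "peonidin", "malvidin", "delphinidin")
#: how many pigments of a family co-occur when the family is expressed
_DEOXY_COUNT_WEIGHTS = (0.6, 0.3, 0.1)
_HYDROXY_COUNT_WEIGHTS = (0.5, 0.25, 0.15, 0.07, 0.03)
#: probability that a 90%-category sample expresses only its majority family
_PURE_DEO_PROB = 0.6
_PURE_HYD_PROB = 0.75


def _family_split(
    rng: np.random.Generator,
    total: float,
    names: tuple[str, ...],
    count_weights: tuple[float, ...],
) -> dict[str, float]:
    """Distribute `total` % over a random subset of a pigment family."""
    if total <= 0:
        return {}
    k = 1 + rng.choice(len(count_weights), p=np.array(count_weights))
    chosen = rng.choice(len(names), size=k, replace=False)
    weights = rng.dirichlet(np.full(k, 1.2))
    return {names[i]: total * w for i, w in zip(chosen, weights) if w > 0}


def make_composition(
    category: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
) -> PigmentComposition:
    """Draw a pigment composition consistent with one chemistry category.

    The deoxy share is 100 (pure) with probability 0.6 or Uniform(91, 100)
    for DEO90, 0 (pure hydroxy) with probability 0.75 or Uniform(0.5, 9)
    for HYD90, and Uniform(10.5, 89.5) for DEO_HYD. Each family's share
    is then spread over a random subset of its members (single-pigment
    families are the most common draw) via a Dirichlet split.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if category == NONE:
        return PigmentComposition(sample_id=sample_id, percentages={})
    if category == DEO90:
        deoxy = 100.0 if rng.random() < _PURE_DEO_PROB else rng.uniform(91.0, 100.0)
    elif category == HYD90:
        deoxy = 0.0 if rng.random() < _PURE_HYD_PROB else rng.uniform(0.5, 9.0)
    elif category == DEO_HYD:
        deoxy = rng.uniform(10.5, 89.5)
    else:
        raise ValueError(f"unknown category {category!r}")
    pcts = _family_split(rng, deoxy, _DEOXY_MEMBERS, _DEOXY_COUNT_WEIGHTS)
    pcts.update(
        _family_split(rng, 100.0 - deoxy, _HYDROXY_MEMBERS, _HYDROXY_COUNT_WEIGHTS)
    )
    return PigmentComposition(sample_id=sample_id, percentages=pcts)


def make_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    label_prefix: str = "s",
) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with labeled extant tips."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the simulator stops at the n-th speciation, so the youngest cherry has
    # zero-length tips (degenerate BM covariance); run time forward by the
    # hold time to the next (censored) speciation, which stays ultrametric
    extra = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = len(str(n_tips))
    taxa = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"{label_prefix}{i:0{width}d}")
    tree.taxon_namespace = taxa
    return Phylogeny(tree=tree)


@dataclass
class StudyDesign:
    """Generating parameters of one synthetic study."""

    n_samples: int = 180
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {
            DEO90: 24 / 180,
            DEO_HYD: 32 / 180,
            HYD90: 96 / 180,
            NONE: 28 / 180,
        }
    )
    n_replicates: int = 2
    birth_rate: float = 1.0
    #: BM rate of the latent trait used to cluster deoxy samples on the tree
    latent_sigma2: float = 1.0
    noise_sd: float = 0.4
    seed: int = 0

    def category_counts(self) -> dict[str, int]:
        props = self.category_proportions
        if abs(sum(props.values()) - 1.0) > 1e-6:
            raise ValueError("category proportions must sum to 1")
        counts = {k: int(round(v * self.n_samples)) for k, v in props.items()}
        # fix rounding drift on the largest category
        drift = self.n_samples - sum(counts.values())
        counts[max(counts, key=counts.get)] += drift
        if any(v < 0 for v in counts.values()):
            raise ValueError("infeasible category mix")
        return counts


@dataclass
class SyntheticStudy:
    """A complete generated dataset plus its ground truth."""

    design: StudyDesign
    tree: Phylogeny
    spectra: SpectrumSet  # replicate-averaged, one per sample
    replicates: dict[str, list[ReflectanceSpectrum]]
    compositions: list[PigmentComposition]
    categories: dict[str, str]
    truth: dict  # every generating parameter, JSON-serializable

    def write(self, out_dir) -> None:
        """Write the delimited files the pipeline readers consume."""
        from .spectra import write_spectra

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spectra(self.spectra, out / "spectra.csv")
        chemistry.write_compositions(self.compositions, out / "compositions.csv")
        (out / "tree.nwk").write_text(self.tree.as_newick() + "\n")
        (out / "ground_truth.json").write_text(json.dumps(self.truth, indent=2))


def make_study(design: StudyDesign | None = None) -> SyntheticStudy:
    """Generate a full synthetic study from a StudyDesign.

    Tips are placed on a pure-birth tree; a latent Brownian trait is
    simulated and the deoxyanthocyanin categories are assigned to the
    tips with the highest latent values, so deoxy production is
    phylogenetically clustered. Pigment category then selects the
    spectral archetype (deoxy flowers are red-step shapes; hydroxy
    flowers span all shapes), coupling chemistry to color the way the
    analysis expects to find it.
    """
    design = design or StudyDesign()
    counts = design.category_counts()
    if design.n_samples < 2:
        raise ValueError("infeasible design: need at least 2 samples")
    rng = np.random.default_rng(design.seed)
    tree = make_tree(design.n_samples, design.birth_rate, seed=int(rng.integers(2**31)))
    tips = tree.tip_labels

    from .phylo import simulate_brownian

    latent = simulate_brownian(
        tree, design.latent_sigma2, seed=int(rng.integers(2**31))
    )[0]
    order = np.argsort(-latent)  # most deoxy-prone first
    categories: dict[str, str] = {}
    deo_block = [tips[i] for i in order[: counts[DEO90] + counts[DEO_HYD]]]
    for j, tip in enumerate(deo_block):
        categories[tip] = DEO90 if j < counts[DEO90] else DEO_HYD
    rest = [tips[i] for i in order[counts[DEO90] + counts[DEO_HYD]:]]
    rest_labels = [HYD90] * counts[HYD90] + [NONE] * counts[NONE]
    rng.shuffle(rest_labels)
    for tip, label in zip(rest, rest_labels):
        categories[tip] = label

    spectra = SpectrumSet()
    replicates: dict[str, list[ReflectanceSpectrum]] = {}
    compositions: list[PigmentComposition] = []
    truth_samples: dict[str, dict] = {}
    for tip in tips:
        category = categories[tip]
        weights = CATEGORY_ARCHETYPE_WEIGHTS[category]
        names = list(weights)
        archetype = names[rng.choice(len(names), p=np.array(list(weights.values())))]
        reps = [
            make_flower_spectrum(
                archetype,
                params={"noise_sd": design.noise_sd},
                rng=rng,
                sample_id=tip,
            )
            for _ in range(design.n_replicates)
        ]
        replicates[tip] = reps
        averaged = average_replicates(reps)[0]
        spectra.add(averaged)
        compositions.append(make_composition(category, rng=rng, sample_id=tip))
        truth_samples[tip] = {"category": category, "archetype": archetype}

    truth = {
        "design": {
            "n_samples": design.n_samples,
            "category_proportions": design.category_proportions,
            "n_replicates": design.n_replicates,
            "birth_rate": design.birth_rate,
            "latent_sigma2": design.latent_sigma2,
            "noise_sd": design.noise_sd,
            "seed": design.seed,
        },
        "category_counts": counts,
        "samples": truth_samples,
    }
    return SyntheticStudy(
        design=design,
        tree=tree,
        spectra=spectra,
        replicates=replicates,
        compositions=compositions,
        categories=categories,
        truth=truth,
    )
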