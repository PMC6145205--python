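"""Synthetic genotype/trait generation for two-locus interaction studies.

Genotypes are independent biallelic markers sampled at Hardy-Weinberg
equilibrium: at minor-allele frequency ``q`` a marker's codes 0/1/2 (minor
allele copies) occur with probabilities ``(1-q)^2, 2q(1-q), q^2``.  The
quantitative trait of a sample is normal noise around a mean set by a 3x3
*penetrance grid* indexed by the genotypes of one causal marker pair,

    y | (g1, g2) = (i, j)  ~  N(f_ij, sigma*),

with ``sigma*`` interpreted as the standard deviation (a ``sigma_as_variance``
switch is provided).  A mixture design sums weighted grid means over several
disjoint causal pairs.  Null datasets draw the trait standard normal,
independent of every marker.

Grid cells take the three canonical mean levels 0.01 (normal), 0.25 (low
risk) and 0.5 (high risk).  Five default grid layouts covering classic
epistasis patterns ship with the package and can be overridden from
YAML/JSON config files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from numpy.typing import NDArray

from .core import GenotypeMatrix
from .membership import assign_crisp_category, build_deviation_scheme

__all__ = [
    "PENETRANCE_LEVELS",
    "PenetranceGrid",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_qt",
    "simulate_dataset",
    "simulate_null",
    "qt_to_ordinal",
    "default_model_grids",
    "load_grid",
]

#: trait mean assigned to normal / low-risk / high-risk genotype combinations
PENETRANCE_LEVELS = {"normal": 0.01, "low_risk": 0.25, "high_risk": 0.5}


@dataclass(frozen=True)
class PenetranceGrid:
    """3x3 mean-trait grid f_ij for one causal two-marker interaction."""

    values: NDArray[np.float64]
    name: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3, 3):
            raise ValueError("penetrance grid must be 3x3")
        object.__setattr__(self, "values", v)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    n: int = 200
    m: int = 100
    maf: float = 0.2
    sigma_star: float = 0.1
    models: Sequence[tuple[PenetranceGrid, tuple[int, int]]] = ()
    weights: Sequence[float] = ()
    seed: int = 0
    sigma_as_variance: bool = False

    def __post_init__(self) -> None:
        if self.models and not self.weights:
            self.weights = [1.0 / len(self.models)] * len(self.models)
        if len(self.weights) != len(self.models):
            raise ValueError("weights length must equal models length")
        used: set[int] = set()
        for _, pair in self.models:
            if used & set(pair):
                raise ValueError("causal marker pairs must be disjoint")
            used |= set(pair)


def simulate_genotypes(
    n: int, m: int, maf: float, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Independent HWE markers; codes count minor-allele copies."""
    if not 0 < maf <= 0.5:
        raise ValueError("minor allele frequency must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = maf
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    codes = rng.choice(3, size=(n, m), p=probs)
    return GenotypeMatrix(codes=codes)


def simulate_qt(genotypes: GenotypeMatrix, config: SimulationConfig,
                rng: np.random.Generator | None = None) -> NDArray[np.float64]:
    """Quantitative trait from the (possibly mixed) penetrance-grid means."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = genotypes.n_samples
    mean = np.zeros(n)
    for w, (grid, (a, b)) in zip(config.weights, config.models):
        if w == 0.0:
            continue
        mean += w * grid.values[genotypes.codes[:, a], genotypes.codes[:, b]]
    sd = np.sqrt(config.sigma_star) if config.sigma_as_variance else config.sigma_star
    return mean + sd * rng.standard_normal(n)


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, NDArray[np.float64]]:
    """Genotypes + trait under one config; fully determined by ``config.seed``.

    The genotype and noise streams use separate child seeds of
    ``config.seed``, so dropping a mixture component by setting its weight
    to 0 reproduces the remaining components' trait exactly.
    """
    g_seed, t_seed = np.random.SeedSequence(config.seed).spawn(2)
    genotypes = simulate_genotypes(config.n, config.m, config.maf, np.random.default_rng(g_seed))
    trait = simulate_qt(genotypes, config, np.random.default_rng(t_seed))
    return genotypes, trait


def simulate_null(
    n: int, m: int, maf: float, seed: int | np.random.Generator
) -> tuple[GenotypeMatrix, NDArray[np.float64]]:
    """Null dataset: HWE genotypes, trait standard normal and independent."""
    if isinstance(seed, np.random.Generator):
        g_rng = t_rng = seed
    else:
        g_seed, t_seed = np.random.SeedSequence(seed).spawn(2)
        g_rng, t_rng = np.random.default_rng(g_seed), np.random.default_rng(t_seed)
    genotypes = simulate_genotypes(n, m, maf, g_rng)
    trait = t_rng.standard_normal(n)
    return genotypes, trait


def qt_to_ordinal(trait: NDArray[np.float64]) -> NDArray[np.int64]:
    """Three ordinal levels cut at sample mean +/- sd/2 (low/middle/high)."""
    scheme = build_deviation_scheme(trait)
    return assign_crisp_category(scheme, trait)


_DEFAULT_LAYOUTS: dict[str, list[list[str]]] = {
    # classic epistasis patterns; N=normal, L=low_risk, H=high_risk
    "model1": [["N", "L", "N"], ["L", "H", "L"], ["N", "L", "N"]],   # checkerboard
    "model2": [["N", "N", "N"], ["N", "H", "H"], ["N", "H", "H"]],   # dominant-dominant
    "model3": [["N", "N", "L"], ["N", "N", "L"], ["L", "L", "H"]],   # recessive-recessive
    "model4": [["N", "N", "L"], ["N", "L", "H"], ["L", "H", "H"]],   # additive threshold
    "model5": [["H", "L", "N"], ["L", "N", "L"], ["N", "L", "H"]],   # diagonal
}
_CODE = {"N": "normal", "L": "low_risk", "H": "high_risk"}


def default_model_grids(
    levels: dict[str, float] | None = None,
    config_dir: str | Path | None = None,
) -> dict[str, PenetranceGrid]:
    """Five named two-locus interaction grids over the canonical levels.

    ``config_dir`` may hold YAML/JSON files (``model1.yaml`` ...) whose 3x3
    arrays override the built-in layout of the same name.
    """
    levels = levels or PENETRANCE_LEVELS
    grids = {}
    for name, layout in _DEFAULT_LAYOUTS.items():
        vals = [[levels[_CODE[c]] for c in row] for row in layout]
        grids[name] = PenetranceGrid(values=np.array(vals), name=name)
    if config_dir is not None:
        for path in sorted(Path(config_dir).glob("*.y*ml")) + sorted(Path(config_dir).glob("*.json")):
            grids[path.stem] = load_grid(path)
    return grids


def load_grid(path: str | Path) -> PenetranceGrid:
    """Read a 3x3 grid from a YAML or JSON file (plain nested list)."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if isinstance(data, dict):
        data = data["values"]
    return PenetranceGrid(values=np.array(data, dtype=float), name=path.stem)
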