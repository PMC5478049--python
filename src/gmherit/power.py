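"""Monte-Carlo power of the heritability LRT over simulation treatments.

Each replicate regenerates a dataset, runs Procrustes alignment, tangent PCA
and the Bonferroni-corrected boundary LRT on the leading PCs, and records
which PCs came out significant. Power per PC is the detection fraction over
replicates, with a binomial standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .gm import gpa_align, tangent_pca
from .kinship import build_army_ant_kinship
from .model import HeritabilityResults, test_top_pcs
from .simulate import SimulatedDataset, Treatment, simulate_dataset

__all__ = ["PowerResult", "analyze_dataset", "estimate_power",
           "power_decay_curve", "replicate_seed"]


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Seed of one replicate: SeedSequence keyed by (master_seed, replicate).

    Replicates are mutually independent streams, and replicate r of a run is
    bit-identical no matter how many replicates the run contains.
    """
    return np.random.SeedSequence([int(master_seed), int(replicate)])


def analyze_dataset(dataset: SimulatedDataset, n_pcs: int = 4,
                    family_alpha: float = 0.05) -> List[HeritabilityResults]:
    """Full per-dataset pipeline: GPA -> tangent PCA -> kinship -> LRTs."""
    shapes = gpa_align(dataset.configs)
    pca = tangent_pca(shapes)
    kin = build_army_ant_kinship(dataset.pedigree,
                                 id_order=[c.specimen_id for c in dataset.configs])
    return test_top_pcs(pca, shapes.centroid_sizes, kin,
                        n_pcs=n_pcs, family_alpha=family_alpha)


@dataclass
class PowerResult:
    """Detection fractions of one treatment at one mating frequency."""

    treatment_name: str
    mating_frequency: int
    n_individuals: int
    n_replicates: int
    detections: np.ndarray  # (R, n_pcs) bool: replicate x PC significance
    seed: int
    hd_magnitude: float

    @property
    def n_pcs(self) -> int:
        return self.detections.shape[1]

    @property
    def power(self) -> np.ndarray:
        """Per-PC fraction of replicates with a significant LRT."""
        return self.detections.mean(axis=0)

    @property
    def se(self) -> np.ndarray:
        p = self.power
        return np.sqrt(p * (1.0 - p) / self.n_replicates)

    def power_pc(self, i: int) -> float:
        """Power of 1-based PC ``i``."""
        return float(self.power[i - 1])


def estimate_power(treatment: Treatment, mating_frequency: int = 2,
                   n_individuals: int = 100, n_replicates: int = 100,
                   seed: int = 0, n_pcs: int = 4,
                   family_alpha: float = 0.05) -> PowerResult:
    """Monte-Carlo power: fraction of replicates whose Bonferroni-corrected
    LRT is significant, per PC.

    Replicate r uses the derived seed (seed, r); results are byte-identical
    to running the replicates one at a time.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    det = np.zeros((n_replicates, n_pcs), dtype=bool)
    for r in range(n_replicates):
        rep_seed = int(replicate_seed(seed, r).generate_state(1, np.uint32)[0]) % (2**31)
        try:
            ds = simulate_dataset(treatment, n=n_individuals,
                                  mating_frequency=mating_frequency,
                                  seed=rep_seed)
            fits = analyze_dataset(ds, n_pcs=n_pcs, family_alpha=family_alpha)
        except Exception as e:
            raise RuntimeError(f"replicate {r} failed: {e}") from e
        det[r] = [f.significant for f in fits]
    return PowerResult(
        treatment_name=treatment.name, mating_frequency=mating_frequency,
        n_individuals=n_individuals, n_replicates=n_replicates,
        detections=det, seed=int(seed),
        hd_magnitude=treatment.spec.hd_magnitude,
    )


def power_decay_curve(base_treatment: Treatment, mating_frequency: int = 2,
                      n_steps: int = 10, min_fraction: float = 0.5,
                      **kwargs) -> List[PowerResult]:
    """Power at effect magnitudes stepped linearly from the treatment's
    standard magnitude down to ``min_fraction`` of it (decreasing order)."""
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    base = base_treatment.spec.hd_magnitude
    magnitudes = np.linspace(base, min_fraction * base, n_steps)
    return [
        estimate_power(base_treatment.with_magnitude(float(m)),
                       mating_frequency=mating_frequency, **kwargs)
        for m in magnitudes
    ]
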