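"""Synthetic case/control microbial-profile generator.

Emulates the structure of a two-class stool-metagenome cohort: a small set
of planted discriminative species whose presence probability differs
between cases and controls, surrounded by uninformative background species
present in both classes at the same rate.  Present-species magnitudes are
drawn log-normal (heavy-tailed, like real relative abundances) and each
sample is renormalised so species plus the unclassified remainder sum to
exactly 100.  Sex and age metadata are generated but do not influence the
abundances unless a stratum effect is configured, which makes
stratification tests honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ProfileDataset
from .exceptions import InvalidParameterError

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe a balanced 60/60 cohort of 30 species with 3
    informative ones at presence probability 0.8 in cases versus 0.1 in
    controls, over a 0.5 background — a strongly but not perfectly
    separable planted signal.

    Parameters
    ----------
    n_case, n_control
        Samples per class.
    n_species
        Total species count F.
    n_informative
        Number of planted discriminative species (<= F).
    prev_case, prev_control
        Presence probability of an informative species in case/control
        samples.
    prev_background
        Presence probability of every uninformative species, both classes.
    lognormal_mu, lognormal_sigma
        Parameters of the log-normal magnitude draw for present species.
    unclassified_mu, unclassified_sigma
        Log-normal parameters of the raw unclassified mass (typically the
        largest single component, as in real profiles).
    age_range
        Inclusive uniform range for the age metadata (the cohort range of
        a typical colorectal-cancer study).
    """

    n_case: int = 60
    n_control: int = 60
    n_species: int = 30
    n_informative: int = 3
    prev_case: float = 0.8
    prev_control: float = 0.1
    prev_background: float = 0.5
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    unclassified_mu: float = 3.0
    unclassified_sigma: float = 0.5
    age_range: tuple = (28, 84)
    case_label: str = "CRC"
    control_label: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise InvalidParameterError("need at least one sample per class")
        if self.n_species < 1:
            raise InvalidParameterError("need at least one species")
        if not 0 <= self.n_informative <= self.n_species:
            raise InvalidParameterError("n_informative must be in [0, n_species]")
        for name in ("prev_case", "prev_control", "prev_background"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"{name} must be a probability, got {p}")


def generate(spec: SyntheticSpec) -> tuple[ProfileDataset, list]:
    """Draw one cohort; returns the dataset and the informative species names.

    Deterministic for a fixed ``spec.seed``.  Presence of species s in
    sample i is Bernoulli with the class- and role-specific probability;
    positive magnitudes are log-normal and the whole sample (species plus
    unclassified) is rescaled to total exactly 100.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    species = [f"s__Species_{i:03d}" for i in range(spec.n_species)]
    informative_idx = np.sort(
        rng.choice(spec.n_species, size=spec.n_informative, replace=False)
    )
    informative = [species[i] for i in informative_idx]

    is_case = np.zeros(n, dtype=bool)
    is_case[: spec.n_case] = True

    prev = np.full((n, spec.n_species), spec.prev_background)
    prev[np.ix_(is_case, informative_idx)] = spec.prev_case
    prev[np.ix_(~is_case, informative_idx)] = spec.prev_control

    present = rng.random((n, spec.n_species)) < prev
    magnitudes = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, (n, spec.n_species))
    raw = np.where(present, magnitudes, 0.0)
    raw_uncl = rng.lognormal(spec.unclassified_mu, spec.unclassified_sigma, n)
    totals = raw.sum(axis=1) + raw_uncl
    scale = 100.0 / totals
    abundance = raw * scale[:, None]
    unclassified = raw_uncl * scale

    sample_ids = [f"case_{i:03d}" for i in range(spec.n_case)] + [
        f"ctrl_{i:03d}" for i in range(spec.n_control)
    ]
    labels = pd.Series(
        np.where(is_case, spec.case_label, spec.control_label), index=sample_ids, name="class"
    )
    metadata = pd.DataFrame(
        {
            "class": labels,
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n),
            "study": "synthetic",
        },
        index=sample_ids,
    )
    dataset = ProfileDataset(
        abundance=pd.DataFrame(abundance, index=sample_ids, columns=species),
        labels=labels,
        unclassified=pd.Series(unclassified, index=sample_ids, name="unclassified"),
        metadata=metadata,
    )
    return dataset, informative
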