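"""Prevalence/abundance selection of analyzable taxa.

Vaginal 16S profiles are sparse: most species are absent from most
women, and a variance-component model fit to a mostly-zero phenotype
has essentially no covariance information.  Heritability is therefore
estimated only for taxa that reach a minimum within-subject proportion
in a minimum fraction of subjects.

Two presets mirror common practice on this kind of data:

* ``PRIMARY`` — present at >= 10% within-subject proportion in >= 20%
  of subjects (the headline analysis set);
* ``EXPANDED`` — >= 1% proportion in >= 2.5% of subjects (a wider
  supplementary set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_cohort import TaxaProportionTable

__all__ = ["FilterSpec", "PRIMARY", "EXPANDED", "select_taxa"]


@dataclass(frozen=True)
class FilterSpec:
    """Joint prevalence/abundance rule for taxon selection.

    A taxon passes when its proportion is at least
    ``min_within_subject_proportion`` in at least ``subject_fraction``
    of subjects (both thresholds inclusive).
    """

    subject_fraction: float
    min_within_subject_proportion: float

    def __post_init__(self):
        for name in ("subject_fraction", "min_within_subject_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


PRIMARY = FilterSpec(subject_fraction=0.20, min_within_subject_proportion=0.10)
EXPANDED = FilterSpec(subject_fraction=0.025, min_within_subject_proportion=0.01)


def select_taxa(
    table: TaxaProportionTable,
    spec: FilterSpec = PRIMARY,
    mode: str = "joint",
) -> list:
    """Return taxa meeting the prevalence/abundance rule, input order.

    ``mode="joint"`` (default) requires the abundance threshold to be
    met in the prevalence fraction of subjects.  ``mode="disjoint"``
    applies the two thresholds separately: nonzero in the prevalence
    fraction of subjects, and meeting the abundance threshold in at
    least one subject.  The joint rule is the default because it is the
    one that guarantees covariance information at the analysis scale.
    """
    if table.n_samples == 0:
        raise ValueError("empty proportion table")
    props = table.proportions
    n = table.n_samples
    if mode == "joint":
        hits = (props >= spec.min_within_subject_proportion).sum(axis=0)
        passing = hits / n >= spec.subject_fraction
    elif mode == "disjoint":
        prevalent = (props > 0).sum(axis=0) / n >= spec.subject_fraction
        abundant = (props >= spec.min_within_subject_proportion).any(axis=0)
        passing = prevalent & abundant
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [t for t, ok in zip(table.taxon_names, passing) if ok]
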