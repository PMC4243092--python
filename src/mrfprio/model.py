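"""Model facade: build once from data, fit in any execution mode.

:class:`DiseaseGeneMRF` bundles the networks, the known genes of the
disease class under study and the complex-derived priors; ``fit()``
dispatches to the imrf1 / imrf2 / deng drivers and returns the
:class:`~mrfprio.inference.SamplerResult` carrying posteriors, the
parameter trace and diagnostics.
"""

from __future__ import annotations

import numpy as np

from .core import PriorVector, build_priors
from .data import ComplexSet, GeneUniverse, NetworkCollection
from .errors import ConfigurationError
from .inference import SamplerConfig, SamplerResult, run_deng, run_imrf1, run_imrf2


class DiseaseGeneMRF:
    """Ising MRF over multiple gene networks for one disease class.

    Parameters
    ----------
    collection
        The K networks over a shared gene universe.
    known_genes
        Indices of the genes known to belong to the disease class; these
        are clamped to label 1 during sampling.
    priors
        Per-gene prior probabilities. If omitted, they are built from
        ``complexes`` (or, with no complexes either, every gene gets the
        genome-wide class rate).
    complexes, all_disease_genes
        Inputs of the complex prior; ``all_disease_genes`` defaults to
        the known genes plus the negative set.
    negative_genes
        Known disease genes of *other* classes. Used as the 0-labelled
        rows of the one-shot estimation in ``deng`` mode and available as
        negative controls for evaluation; they are never clamped.
    """

    def __init__(
        self,
        collection: NetworkCollection,
        known_genes,
        priors: PriorVector | None = None,
        complexes: ComplexSet | None = None,
        all_disease_genes=None,
        negative_genes=(),
        alpha_mode: str = "global",
    ):
        self.collection = collection
        self.known_genes = frozenset(int(g) for g in known_genes)
        if not self.known_genes:
            raise ConfigurationError("known_genes must be non-empty")
        self.negative_genes = frozenset(int(g) for g in negative_genes)
        self.alpha_mode = alpha_mode
        if priors is None:
            if all_disease_genes is None:
                all_disease_genes = self.known_genes | self.negative_genes
            priors = build_priors(
                collection.n_genes,
                complexes,
                self.known_genes,
                frozenset(all_disease_genes),
            )
        if len(priors) != collection.n_genes:
            raise ConfigurationError("priors do not cover the universe")
        self.priors = priors

    @classmethod
    def from_scenario(cls, scenario, **kwargs) -> "DiseaseGeneMRF":
        """Build from a :class:`~mrfprio.synthetic.BenchmarkScenario`."""
        return cls(
            scenario.collection,
            scenario.known,
            complexes=scenario.complexes,
            negative_genes=scenario.negative_controls,
            **kwargs,
        )

    def fit(self, mode: str = "imrf2", config: SamplerConfig | None = None,
            **kwargs) -> SamplerResult:
        """Run the Gibbs sampler in the chosen mode.

        Extra keyword arguments override :class:`SamplerConfig` fields;
        the model's ``alpha_mode`` is used unless overridden.
        """
        if config is None:
            kwargs.setdefault("alpha_mode", self.alpha_mode)
            config = SamplerConfig(**kwargs)
        elif kwargs:
            raise ConfigurationError("pass either a config object or field overrides")
        if mode == "imrf1":
            return run_imrf1(self.collection, sorted(self.known_genes),
                             self.priors, config)
        if mode == "imrf2":
            return run_imrf2(self.collection, sorted(self.known_genes),
                             self.priors, config)
        if mode == "deng":
            return run_deng(self.collection, sorted(self.known_genes),
                            sorted(self.negative_genes), self.priors, config)
        raise ConfigurationError(f"unknown mode: {mode!r}")
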