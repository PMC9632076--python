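"""Model-object interface for demographic ABC inference.

`DemographicABC` bundles an observed haplotype alignment with a set of
candidate demographic scenarios; `fit()` simulates the reference table,
summarizes the observation, performs rejection and returns an
`ABCResults` carrying model posteriors, accepted parameter draws and
diagnostics, with a `summary()` table and plotting helpers.

Typical use::

    from mitoabc import DemographicABC

    mod = DemographicABC.from_files("aln.fasta", "meta.tsv")
    res = mod.fit(n_sims=5000, tolerance=0.05, seed=1)
    print(res.summary())
    res.plot_posterior()
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coalescent import HaplotypeAlignment, build_reference_table
from .demography import SCENARIOS, build_model, default_config
from .rejection import ABCResult, ReferenceTable, cross_validate, reject
from .sumstats import SummaryVector, summarize


class DemographicABC:
    """Rejection-ABC model choice over demographic scenarios.

    Parameters
    ----------
    alignment
        The observed haplotype alignment with per-sample deme labels.
    scenarios
        Candidate scenario names (default: all four).
    config
        Model configuration mapping (default: the packaged 13-deme layout);
        its deme section must match the alignment's deme labels.
    """

    def __init__(
        self,
        alignment: HaplotypeAlignment,
        scenarios: tuple[str, ...] = SCENARIOS,
        config: dict | None = None,
    ) -> None:
        self.alignment = alignment
        self.config = config if config is not None else default_config()
        self.models = [build_model(name, self.config) for name in scenarios]
        self.deme_order = self.models[0].deme_ids
        observed_demes = set(alignment.deme_ids)
        known = set(self.deme_order)
        unknown = sorted(observed_demes - known)
        if unknown:
            raise ValueError(
                f"metadata contains demes absent from the model "
                f"configuration: {unknown}"
            )
        self.observed: SummaryVector = summarize(alignment, self.deme_order)

    @classmethod
    def from_files(
        cls,
        fasta_path: str | Path,
        metadata_path: str | Path,
        scenarios: tuple[str, ...] = SCENARIOS,
        config: dict | None = None,
    ) -> "DemographicABC":
        """Build from an aligned FASTA and a sample-metadata TSV."""
        from .synthetic import read_observed

        aln = read_observed(fasta_path, metadata_path)
        return cls(aln, scenarios=scenarios, config=config)

    def simulate_reference(self, n_sims: int, seed: int) -> ReferenceTable:
        """Simulate the reference table: ``n_sims`` rows per scenario."""
        return build_reference_table(self.models, n_sims, seed)

    def fit(
        self,
        n_sims: int = 5_000,
        tolerance: float = 0.05,
        seed: int = 0,
        reference: ReferenceTable | None = None,
    ) -> "ABCResults":
        """Run simulate -> summarize -> reject and wrap the outcome.

        A pre-built ``reference`` table (e.g. loaded from CSV) skips the
        simulation step.
        """
        table = (reference if reference is not None
                 else self.simulate_reference(n_sims, seed))
        obs = pd.Series(self.observed.to_dict())
        result = reject(table, obs, tolerance)
        return ABCResults(self, table, result)


class ABCResults:
    """Fitted results: posteriors, accepted draws, diagnostics."""

    def __init__(
        self,
        model: DemographicABC,
        reference: ReferenceTable,
        result: ABCResult,
    ) -> None:
        self.model = model
        self.reference = reference
        self.result = result

    @property
    def model_posteriors(self) -> pd.Series:
        return self.result.model_posteriors

    @property
    def best_model(self) -> str:
        return self.result.best_model

    def param_quantiles(self, model_name: str) -> pd.DataFrame:
        return self.result.param_quantiles(model_name)

    def cross_validate(
        self, n_pseudo: int, seed: int = 0
    ) -> pd.DataFrame:
        """Leave-one-out confusion matrix at this fit's tolerance."""
        rng = np.random.default_rng(seed)
        return cross_validate(
            self.reference, n_pseudo, self.result.tolerance, rng
        )

    def summary(self) -> str:
        """Human-readable summary of the model-choice fit."""
        r = self.result
        lines = [
            "Rejection-ABC model choice",
            "=" * 58,
            f"Reference rows:     {r.n_rows}"
            f"  ({r.n_rows // len(self.reference.models)} per model)",
            f"Tolerance:          {r.tolerance}",
            f"Accepted rows:      {len(r.accepted_idx)}",
            f"Statistics used:    {len(r.scaling.names)}"
            + (f"  (dropped {len(r.scaling.dropped)} zero-SD)"
               if r.scaling.dropped else ""),
            "-" * 58,
            f"{'model':<16}{'posterior':>12}{'accepted':>12}",
        ]
        counts = pd.Series(
            self.reference.df["model"].to_numpy()[r.accepted_idx]
        ).value_counts()
        for name, p in r.model_posteriors.items():
            lines.append(
                f"{name:<16}{p:>12.4f}{int(counts.get(name, 0)):>12}"
            )
        lines.append("-" * 58)
        lines.append(f"Best model:         {r.best_model}")
        best_q = self.param_quantiles(r.best_model)
        if best_q.shape[1] > 0:
            lines.append("Posterior quantiles of the best model's parameters:")
            lines.append(best_q.to_string(float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)

    def plot_posterior(self, ax=None):
        """Bar chart of the model posterior probabilities."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        post = self.model_posteriors
        ax.bar(range(len(post)), post.to_numpy(), color="steelblue")
        ax.set_xticks(range(len(post)))
        ax.set_xticklabels(post.index, rotation=30, ha="right")
        ax.set_ylabel("posterior probability")
        ax.set_ylim(0, 1)
        ax.set_title("ABC model choice")
        return ax
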