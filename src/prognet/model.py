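"""Model/Results interface over the module-network prognosis pipeline.

:class:`PrognosticModuleModel` is constructed from an expression matrix and
a clinical table; :meth:`fit` runs the whole chain — rank-based
co-expression network, dense-module detection, permutation-tested module
network, resampled Cox profiling, GeneRank prioritization, top-fraction
selection — and returns a :class:`PrognosticModuleResults` that carries
every intermediate artifact plus evaluation helpers (risk scoring, group
stratification, Dscore, enrichment) for held-out cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from . import coexpression, crosstalk, enrichment, generank, mcode, prognostic, survival
from .config import PipelineSettings
from .io import ClinicalTable, ExpressionMatrix, align_samples, load_clinical, load_expression

logger = logging.getLogger(__name__)

__all__ = ["PrognosticModuleModel", "PrognosticModuleResults"]


class PrognosticModuleModel:
    """Prognostic-module discovery model for one training cohort.

    Parameters
    ----------
    expression
        Training cohort expression matrix (genes × samples), pre-normalized.
    clinical
        Survival time and event status per sample; samples are aligned with
        the matrix by intersection.
    settings
        Full :class:`PipelineSettings`; individual keyword overrides win
        over it.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        clinical: ClinicalTable,
        settings: PipelineSettings | None = None,
        **overrides,
    ):
        base = settings or PipelineSettings()
        if overrides:
            base = replace(base, **overrides)
        self.settings = base
        self.expression, self.clinical = align_samples(expression, clinical)

    @classmethod
    def from_files(cls, expression_path, clinical_path, probe_map=None,
                   settings: PipelineSettings | None = None, **overrides):
        expr = load_expression(expression_path, probe_map=probe_map)
        clin = load_clinical(clinical_path)
        return cls(expr, clin, settings=settings, **overrides)

    def fit(self, n_select: int | None = None) -> "PrognosticModuleResults":
        """Run the full pipeline and return the fitted results object."""
        s = self.settings
        corr = coexpression.pearson_matrix(self.expression)
        network = coexpression.build_rank_network(corr, k=s.k_neighbors,
                                                  ranking=s.ranking)
        qc = coexpression.powerlaw_fit(network)
        logger.info("co-expression network: %d nodes, %d union edges "
                    "(%d selections), mean neighbors %.2f",
                    network.number_of_nodes(), qc.union_edge_count,
                    qc.selection_count, qc.mean_neighbors)

        modules = mcode.detect_modules(
            network,
            node_score_cutoff=s.node_score_cutoff,
            haircut=s.haircut,
            fluff=s.fluff,
            min_size=s.min_module_size,
            k_core_param=s.k_core_param,
        )
        logger.info("detected %d modules of size >= %d", len(modules),
                    s.min_module_size)
        if len(modules) < 2:
            raise ValueError(
                f"only {len(modules)} modules detected; cannot build a module network"
            )

        perm_cfg = crosstalk.PermutationConfig(
            n_permutations=s.n_permutations, alpha=s.crosstalk_alpha,
            seed=s.stage_seed("crosstalk"),
        )
        module_network = crosstalk.build_module_network(network, modules, perm_cfg)

        res_cfg = prognostic.ResampleConfig(
            n_rep=s.n_rep, sample_fraction=s.sample_fraction,
            cox_alpha=s.cox_alpha, seed=s.stage_seed("resample"),
        )
        profiles = prognostic.profile_all(self.expression, modules,
                                          self.clinical, res_cfg)

        rank = generank.generank_network(
            module_network, profiles, d=s.damping,
            method=s.generank_method, tol=s.generank_tol,
        )
        selected = generank.select_top(rank, fraction=s.top_fraction,
                                       module_count=len(modules),
                                       n_select=n_select)
        control = generank.select_control(profiles, len(selected))
        logger.info("selected %d modules by GeneRank: %s", len(selected), selected)

        return PrognosticModuleResults(
            model=self,
            correlation=corr,
            network=network,
            network_qc=qc,
            modules=modules,
            module_network=module_network,
            profiles=profiles,
            generank_result=rank,
            selected_modules=tuple(selected),
            control_modules=tuple(control),
        )


class PrognosticModuleResults:
    """Fitted artifacts of :class:`PrognosticModuleModel` and evaluators."""

    def __init__(self, model, correlation, network, network_qc, modules,
                 module_network, profiles, generank_result,
                 selected_modules, control_modules):
        self.model = model
        self.settings: PipelineSettings = model.settings
        self.correlation: pd.DataFrame = correlation
        self.network: nx.Graph = network
        self.network_qc: coexpression.NetworkQC = network_qc
        self.modules: list[mcode.Module] = modules
        self.module_network: nx.Graph = module_network
        self.profiles: list[prognostic.PrognosticProfile] = profiles
        self.generank_result: generank.GeneRankResult = generank_result
        self.selected_modules: tuple[int, ...] = selected_modules
        self.control_modules: tuple[int, ...] = control_modules
        self._by_id = {m.module_id: m for m in modules}

    # ------------------------------------------------------------------ views

    def module(self, module_id: int) -> mcode.Module:
        return self._by_id[module_id]

    def selected_genes(self, which: str = "selected") -> set[str]:
        """Union of member genes of the selected (or control) modules."""
        ids = self.selected_modules if which == "selected" else self.control_modules
        out: set[str] = set()
        for mid in ids:
            out |= set(self._by_id[mid].genes)
        return out

    def profiles_frame(self) -> pd.DataFrame:
        return prognostic.profiles_to_frame(self.profiles)

    def ranking_frame(self) -> pd.DataFrame:
        """GeneRank table: importance, rank, selection flag per module."""
        rank = self.generank_result
        prof = self.profiles_frame()
        rows = []
        for position, mid in enumerate(rank.ranking, start=1):
            rows.append({
                "module_id": mid,
                "generank": rank.score_of(mid),
                "rank": position,
                "selected": mid in self.selected_modules,
                "sig_frequency": int(prof.loc[mid, "sig_frequency"]),
                "mean_coefficient": float(prof.loc[mid, "mean_coefficient"]),
            })
        return pd.DataFrame(rows).set_index("module_id")

    def modules_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module_id": [m.module_id for m in self.modules],
                "score": [m.mcode_score for m in self.modules],
                "size": [m.size for m in self.modules],
                "genes": [",".join(m.sorted_genes) for m in self.modules],
            }
        ).set_index("module_id")

    # ------------------------------------------------------------- evaluation

    def risk_scores(self, expression: ExpressionMatrix,
                    which: str = "selected") -> pd.Series:
        ids = self.selected_modules if which == "selected" else self.control_modules
        mods = [self._by_id[i] for i in ids]
        return survival.risk_scores(expression, mods, self.profiles)

    def evaluate(self, expression: ExpressionMatrix, clinical: ClinicalTable,
                 which: str = "selected") -> survival.RiskAssessment:
        """Score a cohort with the selected modules, split at the median
        rank and run the log-rank / hazard-ratio evaluation."""
        scores = self.risk_scores(expression, which=which)
        return survival.split_and_test(scores, clinical)

    def dscore(self, datasets: Sequence[tuple[ExpressionMatrix, ClinicalTable]],
               which: str = "selected") -> tuple[float, list[survival.RiskAssessment]]:
        """Per-dataset assessments and their aggregate Dscore."""
        assessments = [self.evaluate(e, c, which=which) for e, c in datasets]
        return survival.dscore([a.logrank_p for a in assessments]), assessments

    def random_geneset_test(self, datasets, n_sets: int = 1000,
                            which: str = "selected") -> survival.RandomSetTest:
        observed, _ = self.dscore(datasets, which=which)
        return survival.random_geneset_test(
            datasets, observed, gene_count=len(self.selected_genes(which)),
            n_sets=n_sets, seed=self.settings.stage_seed("randomsets"),
        )

    def enrich(self, annotations: Mapping[str, Iterable[str]],
               universe: Iterable[str] | None = None,
               which: str = "selected") -> pd.DataFrame:
        """Hypergeometric enrichment of the selected-module genes.

        The default universe is every gene in the co-expression network.
        """
        uni = set(universe) if universe is not None else set(self.network.nodes())
        return enrichment.enrich_many(self.selected_genes(which), annotations, uni)

    # ---------------------------------------------------------------- summary

    def summary(self) -> str:
        qc = self.network_qc
        lines = [
            "Prognostic module network analysis",
            "=" * 50,
            f"genes x samples          {self.model.expression.shape[0]} x {self.model.expression.shape[1]}",
            f"co-expression network    {self.network.number_of_nodes()} nodes, "
            f"{qc.union_edge_count} edges ({qc.selection_count} selections)",
            f"mean neighbors           {qc.mean_neighbors:.2f}",
        ]
        if qc.powerlaw_applicable:
            lines.append(
                f"power-law degree fit     correlation {qc.powerlaw_correlation:.3f}, "
                f"R^2 {qc.powerlaw_r2:.3f}"
            )
        lines += [
            f"modules (size >= {self.settings.min_module_size})        {len(self.modules)}",
            f"module-network edges     {self.module_network.number_of_edges()} "
            f"(alpha {self.settings.crosstalk_alpha}, "
            f"{self.settings.n_permutations} permutations)",
            f"Cox resampling           {self.settings.n_rep} reps on "
            f"{self.settings.sample_fraction:.0%} of samples",
            f"GeneRank damping d       {self.settings.damping}",
            f"selected modules         {list(self.selected_modules)}",
            f"control modules          {list(self.control_modules)}",
            "",
            "top of ranking:",
        ]
        frame = self.ranking_frame().head(10)
        lines.append(frame.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<PrognosticModuleResults: {len(self.modules)} modules, "
                f"{len(self.selected_modules)} selected>")
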