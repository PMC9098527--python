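"""End-to-end orchestration: simulate → process → quantify → profile → ordinate.

A :class:`PipelineConfig` (single declarative mapping, YAML-loadable)
drives every stage; the run writes the panel concentration matrix, per-line
summaries, chemo-marker frequencies, PCA/PCoA/CA tables, a UPGMA Newick
tree and a JSON manifest recording the seed, a config hash and package
versions. Identical config + seed reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chemometrics import correspondence_analysis, hclust, pca, pcoa
from .profiling import (
    KjeldahlParams,
    PanelMatrix,
    chemomarker_report,
    kjeldahl_protein,
    panel_summary,
)
from .quantify import quantify_spectrum
from .signature import load_signature_library
from .simulate import (
    AcquisitionParams,
    read_panel,
    simulate_panel,
    write_panel,
)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    ``panel`` holds :func:`seedqnmr.simulate.simulate_panel` keyword
    arguments (``n_lines``, ``presence_prob``, ``conc_lognormal``);
    ``acquisition`` holds :class:`AcquisitionParams` fields; ``tolerances``
    the assignment window and SNR threshold; ``analysis`` the ordination
    scaling, clustering linkage and chemo-marker threshold. ``input_dir``,
    when set, skips simulation and reads spectra (two-column CSVs plus a
    panel manifest) from disk. Kjeldahl titres for the simulated panel are
    drawn per line so that crude protein spans the 13–40% range typical of
    a diverse legume panel.
    """

    seed: int = 0
    n_lines: int = 96
    input_dir: str | None = None
    write_spectra: bool = False
    acquisition: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=lambda: {"tol_ppm": 0.02, "min_snr": 3.0})
    analysis: dict = field(
        default_factory=lambda: {
            "scale": "center",
            "linkage": "average",
            "metric": "euclidean",
            "min_fraction": 0.95,
        }
    )
    protein: dict = field(
        default_factory=lambda: {
            "V_blank": 0.2,
            "normality": 0.1,
            "sample_mass_g": 0.25,
            "range_pct": [13.0, 40.0],
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_lines": self.n_lines,
            "input_dir": self.input_dir,
            "write_spectra": self.write_spectra,
            "acquisition": dict(self.acquisition),
            "panel": dict(self.panel),
            "tolerances": dict(self.tolerances),
            "analysis": dict(self.analysis),
            "protein": dict(self.protein),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _simulate_protein(config: PipelineConfig, line_ids: list[str]) -> dict[str, float]:
    """Synthetic per-line Kjeldahl titres → crude protein %, seeded."""
    p = config.protein
    lo, hi = p.get("range_pct", [13.0, 40.0])
    rng = np.random.default_rng(config.seed + 10_007)
    out: dict[str, float] = {}
    for line_id in line_ids:
        target = float(rng.uniform(lo, hi))
        # invert the titre formula to get V_sample for the target protein %
        v = p["V_blank"] + target / 6.25 * p["sample_mass_g"] / (
            p["normality"] * 1.4007
        )
        params = KjeldahlParams(
            V_sample=v,
            V_blank=p["V_blank"],
            normality=p["normality"],
            sample_mass_g=p["sample_mass_g"],
        )
        out[line_id] = kjeldahl_protein(params)
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write all outputs; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = load_signature_library()
    outputs: list[str] = []

    def _stage(name):
        logger.info("stage %s", name)

    try:
        _stage("simulate")
        if config.input_dir:
            spectra, truths = read_panel(config.input_dir)
        else:
            params = AcquisitionParams(**config.acquisition)
            spectra, truths = simulate_panel(
                config.n_lines,
                seed=config.seed,
                params=params,
                library=library,
                **config.panel,
            )
            if config.write_spectra:
                write_panel(spectra, truths, out / "spectra")
                outputs.append("spectra/panel_manifest.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"simulate stage failed: {e}") from e

    try:
        _stage("quantify")
        profiles = []
        for spec in spectra:
            profiles.append(
                quantify_spectrum(
                    spec,
                    library=library,
                    tol_ppm=config.tolerances.get("tol_ppm", 0.02),
                    min_snr=config.tolerances.get("min_snr", 3.0),
                )
            )
            logger.info("quantified line %s", spec.meta.get("line_id", "?"))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"quantify stage failed: {e}") from e

    try:
        _stage("profile")
        protein = _simulate_protein(config, [p.line_id for p in profiles])
        panel = PanelMatrix.from_profiles(profiles, library, protein_pct=protein)
        panel.to_csv(out / "panel_matrix.csv")
        outputs.append("panel_matrix.csv")
        summary = panel_summary(panel, library)
        summary.to_csv(out / "panel_summary.csv", index=False, float_format="%.6g")
        outputs.append("panel_summary.csv")
        markers = chemomarker_report(
            panel, min_fraction=config.analysis.get("min_fraction", 0.95)
        )
        markers.to_csv(out / "chemomarkers.csv", index=False, float_format="%.6g")
        outputs.append("chemomarkers.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"profile stage failed: {e}") from e

    try:
        _stage("ordinate")
        scale = config.analysis.get("scale", "center")
        res_pca = pca(panel, scale=scale)
        res_pca.to_csv(str(out / "pca"))
        outputs += ["pca_eigenvalues.csv", "pca_scores.csv", "pca_loadings.csv"]
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(panel.conc.to_numpy()))
        res_pcoa = pcoa(D, labels=panel.line_ids)
        res_pcoa.to_csv(str(out / "pcoa"))
        outputs += ["pcoa_eigenvalues.csv", "pcoa_scores.csv"]
        # CA needs strictly positive margins: drop all-zero columns (metabolites
        # absent across the whole panel)
        nz = panel.conc.loc[:, panel.conc.sum(axis=0) > 0]
        nz = nz.loc[nz.sum(axis=1) > 0, :]
        if nz.shape[0] >= 2 and nz.shape[1] >= 2:
            res_ca = correspondence_analysis(nz)
            res_ca.to_csv(str(out / "ca"))
            outputs += ["ca_eigenvalues.csv", "ca_scores.csv", "ca_loadings.csv"]
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"ordinate stage failed: {e}") from e

    try:
        _stage("cluster")
        tree = hclust(
            panel,
            metric=config.analysis.get("metric", "euclidean"),
            linkage=config.analysis.get("linkage", "average"),
        )
        (out / "hca_upgma.nwk").write_text(tree.to_newick() + "\n")
        outputs.append("hca_upgma.nwk")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"cluster stage failed: {e}") from e

    import pandas as pd
    import scipy

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_lines": len(spectra),
        "outputs": sorted(outputs),
        "versions": {
            "seedqnmr": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
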