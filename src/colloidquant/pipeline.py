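"""Pipeline orchestration: simulate → quantify → fit → decompose → correlate.

A :class:`RunConfig` selects stages and carries every parameter and seed;
:func:`run_pipeline` executes the selected stages in dependency order,
writes standard-format artifacts (16-bit TIFF per channel, tidy CSVs with
header rows, JSON configs) into the output directory, and finishes with a
``manifest.json`` listing every output file with its SHA-256 hash.  The
same config and seed always reproduce the same manifest.  A machine-
readable run log (JSON lines) records the parameters and seed of every
stage executed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, mechanism, synthetic
from .curves import fit_pka
from .imaging import ChannelConfig, Micrograph, Treatment, default_quant_config
from .synthetic import CompoundParams, PanelSpec, SceneParams

logger = logging.getLogger("colloidquant")

STAGES = (
    "simulate-images",
    "quantify",
    "simulate-curves",
    "fit-pka",
    "simulate-panel",
    "mechanism",
    "correlate",
)

EXIT_OK = 0
EXIT_BAD_INPUT = 2
EXIT_NUMERICAL = 3


@dataclass
class TitrationSpec:
    compound: str
    pka: float
    background: float = 10.0
    maximum: float = 1000.0
    noise_sd: float = 0.0
    relative_noise_sd: float = 0.0


@dataclass
class RunConfig:
    """Everything one pipeline run needs; JSON round-trips losslessly."""

    stages: list[str]
    out_dir: str
    seed: int = 0
    # simulate-images / quantify
    n_replicates: int = 1
    images_per_replicate: int = 3
    scene: SceneParams = field(default_factory=SceneParams)
    quant: dict[str, ChannelConfig] = field(
        default_factory=default_quant_config
    )
    # simulate-curves / fit-pka
    titrations: list[TitrationSpec] = field(default_factory=list)
    ph_grid: list[float] = field(
        default_factory=lambda: list(np.arange(3.0, 10.01, 0.5))
    )
    # simulate-panel / mechanism / correlate
    panel: PanelSpec | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for cfg in d["quant"].values():
            if not np.isfinite(cfg["max_area"]):
                cfg["max_area"] = None
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["scene"] = SceneParams(**d["scene"])
        quant = {}
        for role, cfg in d["quant"].items():
            if cfg.get("max_area") is None:
                cfg["max_area"] = np.inf
            quant[role] = ChannelConfig(**cfg)
        d["quant"] = quant
        d["titrations"] = [TitrationSpec(**t) for t in d["titrations"]]
        if d.get("panel") is not None:
            d["panel"]["compounds"] = [
                CompoundParams(**c) for c in d["panel"]["compounds"]
            ]
            d["panel"] = PanelSpec(**d["panel"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing input file {path}"
        )
    return path


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.written: list[Path] = []
        self.log_records: list[dict] = []

    def record(self, path: Path) -> Path:
        self.written.append(path)
        return path

    def log(self, stage: str, **params) -> None:
        rec = {"stage": stage, "seed": self.config.seed, **params}
        self.log_records.append(rec)
        logger.info("stage %s: %s", stage, params)

    # ---- stages ----------------------------------------------------------

    def simulate_images(self) -> None:
        cfg = self.config
        meta_rows = []
        img_dir = self.out / "images"
        idx = 0
        for rep in range(cfg.n_replicates):
            well = f"well_{rep + 1:02d}"
            for k in range(cfg.images_per_replicate):
                stem = f"img_{idx:03d}"
                channels, truth = synthetic.generate_micrograph(
                    cfg.scene, seed=cfg.seed + idx
                )
                for p in synthetic.write_micrograph(
                    channels, truth, img_dir, stem
                ):
                    self.record(p)
                meta_rows.append(
                    {"stem": stem, "well_id": well, "replicate": rep,
                     "compound": "synthetic", "concentration_um": 5.0,
                     "blocker": False}
                )
                idx += 1
        meta = pd.DataFrame(meta_rows)
        path = self.record(self.out / "image_metadata.csv")
        meta.to_csv(path, index=False)
        self.log("simulate-images", n_images=idx,
                 scene=dataclasses.asdict(cfg.scene))

    def quantify(self) -> None:
        cfg = self.config
        meta = pd.read_csv(
            _require(self.out / "image_metadata.csv", "quantify")
        )
        img_dir = self.out / "images"
        rows = []
        per_image: dict[str, imaging.ImageCounts] = {}
        for _, row in meta.iterrows():
            stem = row["stem"]
            channels = synthetic.read_micrograph_channels(img_dir, stem)
            m = Micrograph(
                channels=channels, well_id=row["well_id"],
                treatment=Treatment(
                    compound=row["compound"],
                    concentration_um=float(row["concentration_um"]),
                    blocker=bool(row["blocker"]),
                ),
            )
            counts = imaging.quantify_image(m, cfg.quant)
            per_image[stem] = counts
            rows.append({"stem": stem, "well_id": row["well_id"],
                         "replicate": row["replicate"],
                         **dataclasses.asdict(counts)})
        counts_df = pd.DataFrame(rows)
        path = self.record(self.out / "image_counts.csv")
        counts_df.to_csv(path, index=False)

        rep_rows = []
        for (well, rep), group in counts_df.groupby(
            ["well_id", "replicate"], sort=True
        ):
            images = [per_image[s] for s in group["stem"]]
            record = imaging.aggregate_replicate(images, well_id=str(well))
            rep_rows.append(
                {"well_id": well, "replicate": rep,
                 "n_images": len(images),
                 "foci_per_cell": record.foci_per_cell,
                 "puncta_per_cell": record.puncta_per_cell,
                 "vesicles_per_cell": record.vesicles_per_cell}
            )
        path = self.record(self.out / "replicate_counts.csv")
        pd.DataFrame(rep_rows).to_csv(path, index=False)
        self.log("quantify", n_images=len(rows))

    def simulate_curves(self) -> None:
        cfg = self.config
        if not cfg.titrations:
            raise ValueError(
                "stage 'simulate-curves': config lists no titrations"
            )
        rows = []
        for j, t in enumerate(cfg.titrations):
            ph, f = synthetic.generate_titration(
                t.pka, t.background, t.maximum, cfg.ph_grid,
                noise_sd=t.noise_sd, seed=cfg.seed + 1000 + j,
                relative_noise_sd=t.relative_noise_sd,
            )
            for p, v in zip(ph, f):
                rows.append({"compound": t.compound, "ph": p,
                             "fluorescence": v})
        path = self.record(self.out / "titrations.csv")
        pd.DataFrame(rows).to_csv(path, index=False)
        self.log("simulate-curves", n_curves=len(cfg.titrations))

    def fit_pka(self) -> None:
        df = pd.read_csv(_require(self.out / "titrations.csv", "fit-pka"))
        rows = []
        for cid, group in df.groupby("compound", sort=True):
            fit = fit_pka(
                group["ph"].to_numpy(), group["fluorescence"].to_numpy()
            )
            rows.append({"compound": cid, "pka": fit.pka,
                         "background": fit.background,
                         "maximum": fit.maximum, "rss": fit.rss,
                         "converged": fit.converged,
                         "ionizable": fit.ionizable})
        path = self.record(self.out / "pka_fits.csv")
        pd.DataFrame(rows).to_csv(path, index=False)
        self.log("fit-pka", n_compounds=len(rows))

    def simulate_panel(self) -> None:
        cfg = self.config
        if cfg.panel is None:
            raise ValueError("stage 'simulate-panel': config has no panel")
        panel = dataclasses.replace(cfg.panel, seed=cfg.seed)
        df = synthetic.generate_mechanism_panel(panel)
        path = self.record(self.out / "panel.csv")
        df.to_csv(path, index=False)
        comp = pd.DataFrame(
            [dataclasses.asdict(c) for c in panel.compounds]
        )
        path = self.record(self.out / "panel_compounds.csv")
        comp.to_csv(path, index=False)
        self.log("simulate-panel", n_compounds=len(panel.compounds),
                 wells_per_compound=panel.wells_per_compound)

    def mechanism(self) -> None:
        panel = pd.read_csv(_require(self.out / "panel.csv", "mechanism"))
        fits = mechanism.fit_mechanism_panel(panel)
        rows = [dataclasses.asdict(f) for f in fits]
        path = self.record(self.out / "mechanism_fits.csv")
        pd.DataFrame(rows).to_csv(path, index=False)
        self.log("mechanism", n_compounds=len(fits))

    def correlate(self) -> None:
        mech = pd.read_csv(
            _require(self.out / "mechanism_fits.csv", "correlate")
        )
        panel = pd.read_csv(_require(self.out / "panel.csv", "correlate"))
        fits = [
            mechanism.MechanismFit(**row)
            for row in mech.to_dict("records")
        ]
        vesicles = (
            panel.groupby("compound")["vesicles_per_cell"].mean().to_dict()
        )
        pka_path = self.out / "pka_fits.csv"
        comp_path = self.out / "panel_compounds.csv"
        if pka_path.exists():
            pka_df = pd.read_csv(pka_path)
            pka = dict(zip(pka_df["compound"], pka_df["pka"]))
        else:
            comp_df = pd.read_csv(_require(comp_path, "correlate"))
            pka = dict(zip(comp_df["compound_id"], comp_df["pka"]))
        join = mechanism.build_compound_summary(fits, pka, vesicles)
        summary = pd.DataFrame(
            [dataclasses.asdict(s) for s in join.summaries]
        )
        path = self.record(self.out / "compound_summary.csv")
        summary.to_csv(path, index=False)
        results = {}
        for pairing in (mechanism.PAIRING_EFFICIENCY,
                        mechanism.PAIRING_INTERCEPT):
            res = mechanism.correlate_mechanism(join.summaries, pairing)
            results[pairing] = {"r": res.r, "n": res.n}
        results["missing"] = join.missing
        path = self.record(self.out / "correlations.json")
        path.write_text(json.dumps(results, indent=1, sort_keys=True))
        self.log("correlate", **{
            k: v["r"] for k, v in results.items()
            if isinstance(v, dict) and "r" in v
        })


_STAGE_METHODS = {
    "simulate-images": _Run.simulate_images,
    "quantify": _Run.quantify,
    "simulate-curves": _Run.simulate_curves,
    "fit-pka": _Run.fit_pka,
    "simulate-panel": _Run.simulate_panel,
    "mechanism": _Run.mechanism,
    "correlate": _Run.correlate,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest.

    Stages run in the fixed dependency order regardless of how they are
    listed.  On failure, the failing stage's partial outputs are removed
    before the exception propagates.  On success the manifest (relative
    path → SHA-256) is also written to ``manifest.json`` in the output
    directory, along with the run config and a JSON-lines run log.
    """
    if not config.stages:
        raise ValueError("empty stage list")
    unknown = [s for s in config.stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}; valid: {STAGES}")

    run = _Run(config)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        before = len(run.written)
        try:
            _STAGE_METHODS[stage](run)
        except Exception:
            for path in run.written[before:]:
                path.unlink(missing_ok=True)
            del run.written[before:]
            raise

    config_path = run.out / "run_config.json"
    config_path.write_text(config.to_json())
    run.written.append(config_path)
    log_path = run.out / "run_log.jsonl"
    log_path.write_text(
        "".join(json.dumps(r, sort_keys=True) + "\n"
                for r in run.log_records)
    )
    run.written.append(log_path)

    manifest = {
        "files": {
            str(p.relative_to(run.out)): _sha256(p)
            for p in sorted(set(run.written))
        }
    }
    (run.out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
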