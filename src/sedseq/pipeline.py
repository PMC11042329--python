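"""End-to-end pipeline orchestration from a single YAML config.

Stages (``simulate`` → ``psup`` → ``scores`` → ``fit``) run in dependency
order; each reads and writes only the documented TSV/JSON formats. Every
stage gets a deterministic sub-seed derived from the global seed by
stable hashing, so any stage can be rerun independently and reruns with
an identical config are byte-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

from sedseq import io
from sedseq.exceptions import ConfigurationError
from sedseq.fraction_quant import MixingRatioEstimator
from sedseq.physical import fit_stress, nested_f_test
from sedseq.scores import condition_scores, score_table, sed_score
from sedseq.synthetic import ConditionSpec, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

KNOWN_STAGES = ("simulate", "psup", "scores", "fit")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2^31) derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


class RunConfig:
    """Validated pipeline configuration.

    Expected YAML structure::

        seed: 1
        stages: [simulate, psup, scores, fit]
        simulate:
          n_transcripts: 2000
          depth: 1.0e6
          dispersion: 100
          alpha_s: 1.0
          alpha_p: 1.0
          conditions:
            - {name: control}
            - {name: stress, mu: 1.5, gene_noise_sd: 0.35}
        psup: {min_counts: 20, method: map}
        scores: {control: control, treated: stress, window_fraction: 0.02, bin_size: 100}
        fit: {terms: full, reduced: nu-only}
    """

    def __init__(self, raw: dict):
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a mapping")
        self.seed = int(raw.get("seed", 0))
        self.stages = list(raw.get("stages", []))
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stages: {unknown}")
        # enforce dependency order regardless of listing order
        self.stages = [s for s in KNOWN_STAGES if s in self.stages]
        self.params = {s: dict(raw.get(s, {}) or {}) for s in KNOWN_STAGES}
        for stage in self.stages[1:]:
            pass  # downstream stages read files; presence is checked at run time

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _conditions(sim_params: dict) -> list[ConditionSpec]:
    specs = sim_params.get("conditions") or [{"name": "control"}, {"name": "stress", "mu": 1.5}]
    out = []
    for spec in specs:
        out.append(ConditionSpec(**spec))
    if not any(c.mu == 0 and c.nu == 0 for c in out):
        raise ConfigurationError("at least one condition must be a control (mu = nu = 0)")
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "products": {}}

    for stage in config.stages:
        seed = stage_seed(config.seed, stage)
        params = config.params[stage]
        logger.info("running stage %s (seed %d)", stage, seed)
        try:
            products = _RUNNERS[stage](params, seed, outdir, manifest)
        except Exception:
            io.write_json(manifest, outdir / "manifest.json")
            logger.error("stage %s failed; partial outputs retained in %s", stage, outdir)
            raise
        manifest["stages"][stage] = {"seed": seed, "params": _echo(params)}
        for name, path in products.items():
            manifest["products"][name] = {
                "path": str(path),
                "sha256": _hash_file(path),
            }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _echo(params: dict) -> dict:
    return {
        k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        for k, v in params.items()
    }


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _run_simulate(params: dict, seed: int, outdir: Path, manifest: dict) -> dict:
    products = {}
    conditions = _conditions(params)
    for i, cond in enumerate(conditions):
        exp = simulate_experiment(
            n_transcripts=int(params.get("n_transcripts", 2000)),
            condition=cond,
            alpha_s=float(params.get("alpha_s", 1.0)),
            alpha_p=float(params.get("alpha_p", 1.0)),
            depth=float(params.get("depth", 1e6)),
            dispersion=float(params.get("dispersion", 100.0)),
            seed=stage_seed(seed, cond.name),
        )
        products[f"counts_{cond.name}"] = io.write_table(
            exp.counts, outdir / f"counts_{cond.name}.tsv"
        )
        truth = exp.true_psup.rename("true_psup").reset_index()
        products[f"truth_{cond.name}"] = io.write_table(
            truth, outdir / f"truth_{cond.name}.tsv"
        )
        if i == 0:
            products["catalog"] = io.write_table(exp.catalog, outdir / "catalog.tsv")
    return products


def _run_psup(params: dict, seed: int, outdir: Path, manifest: dict) -> dict:
    products = {}
    for counts_path in sorted(outdir.glob("counts_*.tsv")):
        name = counts_path.stem.removeprefix("counts_")
        counts = io.read_counts(counts_path)
        est = MixingRatioEstimator(
            min_counts=int(params.get("min_counts", 20)),
            method=params.get("method", "map"),
            seed=seed,
        )
        psup = est.fit_transform(counts)
        products[f"psup_{name}"] = io.write_table(psup, outdir / f"psup_{name}.tsv")
        products[f"ratios_{name}"] = io.write_json(
            dataclasses.asdict(est.ratios_), outdir / f"ratios_{name}.json"
        )
    return products


def _load_scored(outdir: Path, name: str, params: dict):
    psup = io.read_table(outdir / f"psup_{name}.tsv")
    lengths = io.read_table(outdir / "catalog.tsv")
    return condition_scores(
        psup, lengths, condition=name, window_fraction=float(params.get("window_fraction", 0.02))
    )


def _run_scores(params: dict, seed: int, outdir: Path, manifest: dict) -> dict:
    control_name = params.get("control", "control")
    treated_name = params.get("treated", "stress")
    control = _load_scored(outdir, control_name, params)
    treated = _load_scored(outdir, treated_name, params)
    lengths = io.read_table(outdir / "catalog.tsv")
    table = score_table(
        control,
        treated,
        psup_replicates_treated=[io.read_table(outdir / f"psup_{treated_name}.tsv")],
        lengths=lengths,
        bin_size=int(params.get("bin_size", 100)),
    )
    # control-condition rSed is the within-condition relative sedimentation
    r_sed_control = sed_score(
        io.read_table(outdir / f"psup_{control_name}.tsv"),
        lengths,
        bin_size=int(params.get("bin_size", 100)),
    )
    table = table.merge(
        r_sed_control.rename("r_sed_control").reset_index(), on="transcript_id", how="left"
    )
    return {"scores": io.write_table(table, outdir / "scores.tsv")}


def _run_fit(params: dict, seed: int, outdir: Path, manifest: dict) -> dict:
    scores = io.read_table(outdir / "scores.tsv")
    L = scores["length_nt"].to_numpy(float)
    # default: fit the windowed treatment averages; per-transcript behind a flag
    if params.get("data", "windowed") == "windowed":
        y_c = scores["mu_L_control"].to_numpy(float)
        y_t = scores["mu_L_treated"].to_numpy(float)
    else:
        y_c = scores["lopsup_control"].to_numpy(float)
        y_t = scores["lopsup_treated"].to_numpy(float)
    full = fit_stress(
        L,
        y_c,
        L,
        y_t,
        terms=params.get("terms", "full"),
        share_baseline=bool(params.get("share_baseline", True)),
    )
    report = {"full": dataclasses.asdict(full)}
    reduced_terms = params.get("reduced", "nu-only")
    if reduced_terms:
        reduced = fit_stress(
            L,
            y_c,
            L,
            y_t,
            terms=reduced_terms,
            share_baseline=bool(params.get("share_baseline", True)),
        )
        test = nested_f_test(full, reduced)
        report["reduced"] = dataclasses.asdict(reduced)
        report["f_test"] = dataclasses.asdict(test)
    return {"fit": io.write_json(report, outdir / "fit.json")}


_RUNNERS = {
    "simulate": _run_simulate,
    "psup": _run_psup,
    "scores": _run_scores,
    "fit": _run_fit,
}
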