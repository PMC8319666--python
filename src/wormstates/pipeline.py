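"""End-to-end screen pipeline: tracks -> speeds -> states -> metrics -> table.

One shared model per experiment: for every gene, the HMM is fitted on
the concurrent control group's speed sequences, frozen, and used to
decode both control and treated animals, so normalized metrics compare
like with like. All randomness derives from one master seed; every
intermediate is written to disk and a run log records the configuration
hash and seeds, making a run fully reproducible from (config, manifest,
seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as wio
from .hmm import fit_baum_welch, speeds_to_obs, viterbi_decode
from .metrics import summarize
from .screen import group_summary, screen_report
from .tracking import compute_speed

logger = logging.getLogger("wormstates")

STAGES = ("read_tracks", "speeds", "fit", "decode", "metrics", "screen")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage
        self.detail = detail


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis; defaults are the assay
    constants (1 frame/s, 30-minute sessions)."""

    frame_rate_hz: float = 1.0
    session_duration_s: float = 1800.0
    window_s: float = 0.0
    max_gap_frames: int = 5
    hmm_init: str = "quantile"
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    hmm_epsilon: float = 0.01
    hmm_restarts: int = 0
    per_animal_fit: bool = False
    alpha: float = 0.05
    family_size: int | None = None
    rule: str = "ratio_band"
    band: float = 0.20
    cutoffs: tuple[float, float] = (0.6, 1.7)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cutoffs" in d:
            d["cutoffs"] = tuple(d["cutoffs"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _animal_states(track, params, config):
    """Speeds -> per-segment decoded states for one animal."""
    segments = compute_speed(track, window_s=config.window_s, max_gap_frames=config.max_gap_frames)
    decoded = []
    for seg in segments:
        obs = speeds_to_obs(seg.speeds, params.epsilon)
        decoded.append(
            viterbi_decode(
                params, obs, animal_id=track.animal_id, times=seg.times, segment_id=seg.segment_id
            )
        )
    return decoded


def run_pipeline(config: PipelineConfig, manifest, outdir) -> "PipelineOutput":
    """Execute the whole workflow for a screen manifest.

    ``manifest`` is a dict (or path to JSON) with a ``genes`` list; each
    entry maps ``gene_label`` to lists of treated and control track-CSV
    paths. Outputs: per-gene fitted parameters (JSON), per-animal decoded
    states (CSV), a per-animal summary table (TSV), the screen table
    (TSV) and a run log (JSON). Any stage failure aborts with the stage
    name and the offending input; partial outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, dict):
        manifest = wio.read_manifest_json(manifest)

    gene_groups = []
    summary_rows = []
    for entry in manifest["genes"]:
        gene = entry["gene_label"]
        tracks = {}
        for role in ("control", "treated"):
            paths = entry.get(role, [])
            if not paths:
                raise PipelineError("read_tracks", f"gene {gene!r} has no {role} tracks")
            role_tracks = []
            for p in paths:
                if not Path(p).exists():
                    raise PipelineError("read_tracks", f"missing file {p}")
                try:
                    role_tracks.append(wio.read_track_csv(p))
                except Exception as exc:
                    raise PipelineError("read_tracks", f"{p}: {exc}") from exc
            tracks[role] = role_tracks

        # fit the shared model on the concurrent control group
        try:
            obs_seqs = []
            for track in tracks["control"]:
                for seg in compute_speed(
                    track, window_s=config.window_s, max_gap_frames=config.max_gap_frames
                ):
                    obs_seqs.append(speeds_to_obs(seg.speeds, config.hmm_epsilon))
            params, trace = fit_baum_welch(
                obs_seqs,
                init=config.hmm_init,
                max_iter=config.hmm_max_iter,
                tol=config.hmm_tol,
                n_restarts=config.hmm_restarts,
                seed=config.seed,
                epsilon=config.hmm_epsilon,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("fit", f"gene {gene!r}: {exc}") from exc
        wio.write_params_json(params, outdir / f"{gene}_params.json")

        group_sums = {}
        for role in ("control", "treated"):
            summaries = []
            for track in tracks[role]:
                try:
                    decoded = _animal_states(track, params, config)
                except Exception as exc:
                    raise PipelineError("decode", f"{track.animal_id}: {exc}") from exc
                if not decoded:
                    logger.warning("animal %s has no decodable segments", track.animal_id)
                    continue
                wio.write_states_csv(decoded, outdir / f"{gene}_{role}_{track.animal_id}_states.csv")
                s = summarize(decoded, frame_rate_hz=config.frame_rate_hz, animal_id=track.animal_id)
                summaries.append(s)
                row = {"gene": gene, "role": role, "animal_id": track.animal_id,
                       "n_valid_frames": s.n_valid_frames}
                row.update(s.metric_dict())
                summary_rows.append(row)
            if not summaries:
                raise PipelineError("metrics", f"gene {gene!r} {role} group is empty after decoding")
            group_sums[role] = group_summary(gene, role, summaries)
        gene_groups.append((gene, group_sums["treated"], group_sums["control"]))

    try:
        table, results = screen_report(
            gene_groups,
            alpha=config.alpha,
            family_size=config.family_size,
            rule=config.rule,
            band=config.band,
            cutoffs=config.cutoffs,
        )
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    import pandas as pd

    summary_df = pd.DataFrame(summary_rows)
    summary_df.to_csv(outdir / "animal_summaries.tsv", sep="\t", index=False)
    table.to_csv(outdir / "screen_table.tsv", sep="\t", index=False)

    from . import __version__

    run_log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_genes": len(gene_groups),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return PipelineOutput(table=table, results=results, summaries=summary_df, run_log=run_log)


@dataclass
class PipelineOutput:
    table: "object"
    results: list
    summaries: "object"
    run_log: dict
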