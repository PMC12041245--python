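"""End-to-end reproducible runs: simulate -> pairs -> extend -> train -> evaluate.

A single global seed fans out deterministically to every stage through a
named-substream scheme (stage name -> child seed via SHA-256), so no stage
reads global RNG state and the whole run is reproducible from one integer.
Stage boundaries log input/output counts (pairs generated, duplicates
removed, negatives built) so dataset accounting is emitted for any corpus,
and a manifest records versions, child seeds and artifact hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .encoder import EncoderConfig, save_checkpoint
from .errors import StateError
from .metrics import evaluate, tfidf_baseline
from .moe import extend
from .pairs import (aggregate, build_eval_set, build_negatives, sample_pairs,
                    split_and_dedup, write_eval_csv, write_pairs_csv)
from .synthetic import (SyntheticConfig, encoder_config_for, generate_corpus,
                        generate_fixture_encoder, vocab_words,
                        write_events_jsonl, write_records_jsonl)
from .training import TrainConfig, fit

logger = logging.getLogger("cociteembed")


def derive_seed(master: int, stage: str) -> int:
    """Deterministic child seed for a named stage (below 2**31)."""
    digest = hashlib.sha256(f"{master}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything one demo run needs; round-trips through YAML unchanged."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    ratio: float = 0.01
    min_citations: int = 15
    n_sampled_pairs: int | None = None
    encoder_blocks: int = 2
    encoder_d_model: int = 128
    encoder_d_ff: int = 256
    with_baseline: bool = True
    log_level: str = "INFO"

    def encoder_config(self) -> EncoderConfig:
        return encoder_config_for(self.synthetic, n_blocks=self.encoder_blocks,
                                  d_model=self.encoder_d_model,
                                  d_ff=self.encoder_d_ff)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["citation_count_range"] = list(
            self.synthetic.citation_count_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        if "citation_count_range" in syn:
            syn["citation_count_range"] = tuple(syn["citation_count_range"])
        tr = dict(d.pop("train", {}))
        return cls(synthetic=SyntheticConfig(**syn), train=TrainConfig(**tr), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full demo pipeline into ``out_dir``; returns the report dict.

    Artifacts written: corpus and citation events (JSONL), train/eval pair
    tables (CSV), the extended checkpoint, training history (JSON lines),
    ``report.json`` (trained / untrained / baseline metric panels) and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stage_seeds = {s: derive_seed(config.seed, s)
                   for s in ("simulate", "sample", "split", "negatives",
                             "init", "train")}
    counts: dict = {}

    def _fail(stage):
        def wrap(fn):
            def inner(*a, **kw):
                try:
                    return fn(*a, **kw)
                except Exception as exc:
                    raise StateError(f"stage {stage!r} failed: {exc}") from exc
            return inner
        return wrap

    # -- simulate ------------------------------------------------------------
    syn = dataclasses.replace(config.synthetic, seed=stage_seeds["simulate"])
    records, events = _fail("simulate")(generate_corpus)(syn)
    write_records_jsonl(records, out / "records.jsonl")
    write_events_jsonl(events, out / "events.jsonl")
    counts["records"] = len(records)
    counts["citation_events"] = len(events)
    logger.info("simulate: %d records, %d events", len(records), len(events))

    # -- pairs ---------------------------------------------------------------
    def _build_pairs():
        pairs = aggregate(events)
        counts["distinct_cocitation_pairs"] = len(pairs)
        cocited_keys = {p.key for p in pairs}
        if config.n_sampled_pairs is not None:
            pairs = sample_pairs(pairs, config.n_sampled_pairs, stage_seeds["sample"])
            counts["sampled_pairs"] = len(pairs)
        split = split_and_dedup(pairs, ratio=config.ratio, seed=stage_seeds["split"])
        negatives = build_negatives(
            records, cocited_keys, config.min_citations,
            n=len(split.eval_positives), seed=stage_seeds["negatives"])
        return split, build_eval_set(split.eval_positives, negatives)

    split, eval_pairs = _fail("build-pairs")(_build_pairs)()
    counts["train_pairs"] = len(split.train)
    counts["eval_positives"] = len(split.eval_positives)
    counts["eval_pairs"] = len(eval_pairs)
    counts["duplicates_removed"] = split.n_duplicates_removed
    write_pairs_csv(split.train, out / "pairs_train.csv")
    write_eval_csv(eval_pairs, out / "pairs_eval.csv")
    logger.info("pairs: %d train / %d eval (%d positives)",
                len(split.train), len(eval_pairs), len(split.eval_positives))

    # -- extend --------------------------------------------------------------
    def _extend():
        base = generate_fixture_encoder(config.encoder_config(),
                                        stage_seeds["init"],
                                        vocab=vocab_words(syn.vocab_size))
        return extend(base, syn.domain_labels)

    moe = _fail("extend")(_extend)()
    record_map = {r.paper_id: r for r in records}
    untrained_report = evaluate(moe, eval_pairs, record_map)

    # -- train ---------------------------------------------------------------
    train_cfg = dataclasses.replace(config.train, seed=stage_seeds["train"])
    trained, history = _fail("train")(fit)(moe, split.train, record_map,
                                           eval_pairs, train_cfg)
    save_checkpoint(trained, out / "checkpoint")
    with open(out / "history.jsonl", "w") as fh:
        for h in history:
            fh.write(json.dumps(h) + "\n")
    counts["train_steps"] = history[-1]["step"] if history else 0

    # -- evaluate ------------------------------------------------------------
    trained_report = _fail("evaluate")(evaluate)(trained, eval_pairs, record_map)
    report = {
        "trained": trained_report.to_dict(),
        "untrained": untrained_report.to_dict(),
        "counts": counts,
    }
    if config.with_baseline:
        table = tfidf_baseline(records)
        report["tfidf"] = evaluate(table, eval_pairs, record_map).to_dict()
    (out / "report.json").write_text(json.dumps(report, indent=2))

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": config.to_dict(),
        "counts": counts,
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: macro F1max %.4f (untrained %.4f)",
                report["trained"]["macro"]["f1_max"],
                report["untrained"]["macro"]["f1_max"])
    return report


_COLUMNS = ("f1_max", "precision", "recall", "threshold", "ratio", "roc_auc")


def render_report(run_dir) -> str:
    """Human-readable metric table for a completed run directory."""
    run_dir = Path(run_dir)
    path = run_dir / "report.json"
    if not path.exists():
        raise StateError(f"{run_dir} holds no report.json (run not evaluated)")
    report = json.loads(path.read_text())
    lines = []
    for section in ("trained", "untrained", "tfidf"):
        if section not in report:
            continue
        lines.append(f"== {section} ==")
        header = f"{'domain':<12}" + "".join(f"{c:>11}" for c in _COLUMNS)
        lines.append(header)
        rows = dict(report[section]["per_domain"])
        rows["macro"] = report[section]["macro"]
        for dom, m in rows.items():
            cells = "".join(
                f"{m[c]:>11.4f}" if m[c] is not None else f"{'n/a':>11}"
                for c in _COLUMNS)
            lines.append(f"{dom:<12}" + cells)
        lines.append("")
    return "\n".join(lines)
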