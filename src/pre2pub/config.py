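"""Run configuration: a flat ``key = value`` file, overridden by CLI flags.

Recognized keys (defaults in parentheses):

* ``author.pair_threshold`` (0.9) — strict lower bound for a name pair match
* ``author.rule_order`` (comma list of the five rules, in fallback order)
* ``similarity.title_threshold`` (0.95), ``similarity.abstract_threshold`` (0.9)
* ``similarity.hash_dim`` (512), ``similarity.backend`` (``hashed`` | ``reference``)
* ``similarity.model_name`` (reference backend checkpoint)
* ``source.retmax`` (5), ``source.cache_dir``, ``source.rate_limit_per_sec`` (3)
* ``date_strictness`` (``strictly_older`` | ``older_or_equal``)
* ``stopwords_path`` (packaged list when unset)

Precedence: built-in default < config file < explicit CLI flag. The resolved
configuration is hashed and logged at the start of every run so any decision
can be replayed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .authors import DEFAULT_RULE_ORDER, AuthorMatchConfig
from .errors import ConfigError
from .pipeline import DateStrictness, PipelineConfig
from .records import AuthorRule
from .similarity import EmbeddingBackend, HashedNgramBackend, SimilarityConfig
from .textnorm import load_stopwords

__all__ = ["RunConfig", "load_config_file", "build_run_config"]

_DEFAULTS: dict[str, str] = {
    "author.pair_threshold": "0.9",
    "author.rule_order": ",".join(r.value for r in DEFAULT_RULE_ORDER),
    "similarity.title_threshold": "0.95",
    "similarity.abstract_threshold": "0.9",
    "similarity.hash_dim": "512",
    "similarity.backend": "hashed",
    "similarity.model_name": "",
    "source.retmax": "5",
    "source.cache_dir": "",
    "source.rate_limit_per_sec": "3",
    "date_strictness": "strictly_older",
    "stopwords_path": "",
}


def load_config_file(path: str | Path) -> dict[str, str]:
    """Parse ``key = value`` lines; ``#`` starts a comment; unknown keys rejected."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _DEFAULTS:
            raise ConfigError(f"{path}:{lineno}: unknown config key '{key}'")
        out[key] = value.strip()
    return out


@dataclass
class RunConfig:
    """Everything one run needs: pipeline config, backend, and provenance hash."""

    pipeline: PipelineConfig
    backend: EmbeddingBackend
    values: dict[str, str] = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.values, sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def build_run_config(
    config_path: str | Path | None = None,
    overrides: Optional[dict[str, str]] = None,
) -> RunConfig:
    values = dict(_DEFAULTS)
    if config_path:
        values.update(load_config_file(config_path))
    for key, val in (overrides or {}).items():
        if key not in _DEFAULTS:
            raise ConfigError(f"unknown config key '{key}'")
        if val is not None:
            values[key] = str(val)

    def _float(key: str) -> float:
        try:
            return float(values[key])
        except ValueError as exc:
            raise ConfigError(f"config key '{key}' must be a number, got {values[key]!r}") from exc

    def _int(key: str) -> int:
        try:
            return int(values[key])
        except ValueError as exc:
            raise ConfigError(f"config key '{key}' must be an integer, got {values[key]!r}") from exc

    try:
        rule_order = tuple(
            AuthorRule(tok.strip()) for tok in values["author.rule_order"].split(",") if tok.strip()
        )
        author_cfg = AuthorMatchConfig(
            pair_threshold=_float("author.pair_threshold"), rule_order=rule_order
        )
        sim_cfg = SimilarityConfig(
            title_threshold=_float("similarity.title_threshold"),
            abstract_threshold=_float("similarity.abstract_threshold"),
        )
        stopwords = load_stopwords(values["stopwords_path"] or None)
        pipeline = PipelineConfig(
            author_cfg=author_cfg,
            sim_cfg=sim_cfg,
            retmax=_int("source.retmax"),
            date_strictness=DateStrictness(values["date_strictness"]),
            stopwords=stopwords,
        )
    except (ValueError, KeyError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc

    if values["similarity.backend"] == "hashed":
        backend: EmbeddingBackend = HashedNgramBackend(dim=_int("similarity.hash_dim"))
    elif values["similarity.backend"] == "reference":
        from .similarity import SentenceTransformerBackend

        model = values["similarity.model_name"]
        if not model:
            raise ConfigError("config key 'similarity.model_name' required for backend=reference")
        backend = SentenceTransformerBackend(model)
    else:
        raise ConfigError(
            f"config key 'similarity.backend' must be 'hashed' or 'reference', "
            f"got {values['similarity.backend']!r}"
        )
    return RunConfig(pipeline=pipeline, backend=backend, values=values)
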