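"""Run configuration: a flat, YAML-serialisable set of thresholds and
options that can be saved and re-used across annotation runs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # input handling
    concatenate: bool = True
    replace_n_runs: bool = False
    n_run_min: int = 12
    grouping: str = "separate"  # separate | grouped
    # gene model
    min_gene_len_nt: int = 90
    start_codons: list[str] = field(default_factory=lambda: ["ATG", "GTG", "TTG"])
    external_gene_model: str | None = None
    # intergenic search
    igorf_enabled: bool = True
    igorf_min_len: int = 60
    igorf_reach: int = 30
    igorf_mode: str = "flattened"  # flattened | oriented
    igorf_evalue: float = 1e-10
    # homology / profiles
    blast_evalue: float = 1e-5
    tigrfam_evalue: float = 1e-5
    prefer_tigrfam_names: bool = True
    add_ec_numbers: bool = True
    stop_keywords: list[str] = field(default_factory=list)
    engine: str = "naive"  # naive | blastp | blastn
    protein_db: str | None = None
    profile_dbs: list[str] = field(default_factory=list)
    # output
    reuse_results: bool = True
    strict_feature_keys: bool = False
    update_existing: bool = False
    preserve_gene_cds: bool = False


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def load_config(path: str | Path, log: list[str] | None = None) -> RunConfig:
    """Load a saved configuration; a missing file restores the defaults and
    unknown keys are ignored with a warning."""
    path = Path(path)
    if not path.exists():
        if log is not None:
            log.append(f"{path}: no saved configuration; defaults loaded")
        return RunConfig()
    data = yaml.safe_load(path.read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    clean = {}
    for key, value in data.items():
        if key not in known:
            if log is not None:
                log.append(f"{path}: unknown configuration key {key!r} ignored")
            continue
        clean[key] = value
    return RunConfig(**clean)
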