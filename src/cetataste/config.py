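"""Pipeline configuration (YAML) and logging setup."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["GeneConfig", "PipelineConfig", "setup_logging"]


def setup_logging(verbose: bool = False) -> logging.Logger:
    logger = logging.getLogger("cetataste")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return logger


@dataclass
class GeneConfig:
    name: str
    alignment: Path
    reference: str
    exons: list[tuple[int, int]] | None = None


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    YAML schema::

        seed: 1                    # mandatory
        tree: path/to/tree.nwk
        output_dir: out/
        genes:
          - name: tas1r1_like
            alignment: path/to/aln.fasta
            reference: Bos
            exons: [[1, 300], [301, 642]]   # optional, 1-based closed nt
        foreground: derive         # or a list of branch names
        models:
          ladder: true
          clade: false
          site: false
          free_ratio: true
        lineages:                  # optional, for the loss summary
          cetacea: [Tursiops, ...]
    """

    seed: int
    tree: Path
    output_dir: Path
    genes: list[GeneConfig]
    foreground: str | list[str] = "derive"
    models: dict = field(default_factory=lambda: {"ladder": True})
    lineages: dict[str, list[str]] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        missing = [k for k in ("seed", "tree", "output_dir", "genes") if k not in raw]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        base = path.parent
        genes = []
        for g in raw["genes"]:
            exons = g.get("exons")
            genes.append(
                GeneConfig(
                    name=g["name"],
                    alignment=(base / g["alignment"]).resolve(),
                    reference=g["reference"],
                    exons=[tuple(x) for x in exons] if exons else None,
                )
            )
        cfg = cls(
            seed=int(raw["seed"]),
            tree=(base / raw["tree"]).resolve(),
            output_dir=(base / raw["output_dir"]).resolve(),
            genes=genes,
            foreground=raw.get("foreground", "derive"),
            models=raw.get("models", {"ladder": True}),
            lineages=raw.get("lineages"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.tree.exists():
            raise FileNotFoundError(f"tree file not found: {self.tree}")
        for g in self.genes:
            if not g.alignment.exists():
                raise FileNotFoundError(
                    f"alignment for gene {g.name!r} not found: {g.alignment}"
                )
        if not self.genes:
            raise ValueError("config lists no genes")
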