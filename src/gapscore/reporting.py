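"""Human-readable narrative report and the per-run provenance manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

from .data_model import GapResult
from .io_config import RunConfig
from .pipeline import DOMAIN_LABELS, dominant_domain


@dataclass
class RunManifest:
    """Provenance record written once per run."""

    command: str
    config: dict
    inputs: dict[str, str]  # path -> sha256
    package_version: str
    seed: Optional[int]
    started_utc: str
    finished_utc: str = ""
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def start(
        cls,
        command: str,
        config: Optional[RunConfig],
        input_paths: list[Union[str, Path]],
        seed: Optional[int] = None,
    ) -> "RunManifest":
        from . import __version__

        digests = {}
        for p in input_paths:
            p = Path(p)
            if p.is_file():
                digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
        return cls(
            command=command,
            config=config.to_dict() if config is not None else {},
            inputs=digests,
            package_version=__version__,
            seed=seed,
            started_utc=datetime.now(timezone.utc).isoformat(),
        )

    def finish(self, out_dir: Union[str, Path], warnings: list[str]) -> Path:
        self.finished_utc = datetime.now(timezone.utc).isoformat()
        self.warnings = list(warnings)
        path = Path(out_dir) / "manifest.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return path


def narrative_report(results: list[GapResult]) -> str:
    """One line per condition: rank, scores, tiers, flag, dominant domain."""
    lines = []
    for r in sorted(results, key=lambda x: x.rank):
        tiers = r.tiers or {}
        tier_txt = ", ".join(
            f"{d} {tiers.get(d, '?')}" for d in ("burden", "cost", "innovation")
        )
        dom = dominant_domain(r)
        if dom == "none":
            dom_txt = "no dominant domain"
        elif dom == "innovation":
            dom_txt = "dominant factor: low biomedical product innovation"
        else:
            dom_txt = f"dominant factor: {DOMAIN_LABELS[dom]}"
        flag = "OPPORTUNITY" if r.opportunity_flag else "-"
        line = (
            f"{r.rank:>2}. {r.name}: overall gap "
            f"{r.overall_gap:.2f} ({tiers.get('overall', '?')}); "
            f"tiers: {tier_txt}; {dom_txt}; {flag}"
        )
        if r.reason:
            line += f" [{r.reason}]"
        lines.append(line)
    return "\n".join(lines)
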