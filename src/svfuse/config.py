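"""Pipeline configuration: every filter threshold and tolerance in one
YAML-serialisable object, named after the rule it governs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import LibrarySpec


@dataclass
class PipelineConfig:
    # read-pair triage
    mapq_threshold: int = 30            # either read below this -> discard
    dedup_max_offset_bp: int = 2        # offset PCR duplicates, per end
    recheck_kmer: int = 13              # realignment-recheck seed size
    # clustering / filtering
    min_support: int = 2                # consistent pairs per junction
    min_span_intra_bp: int = 10_000     # intra-chromosomal minimum span
    # copy-number integration
    step_threshold_log2: float = 0.3
    min_probes: int = 5
    step_match_tolerance_bp: int = 10_000
    baseline_ploidy: float = 2.0
    # fusion prediction
    runthrough_window_bp: int = 1_000_000
    # junction sequence analysis
    shard_min_len_bp: int = 10
    junction_flank_bp: int = 200
    # randomness
    seed: int = 0
    libraries: list = field(default_factory=list)

    def lib_specs(self) -> dict:
        out = {}
        for entry in self.libraries:
            spec = entry if isinstance(entry, LibrarySpec) else LibrarySpec(**entry)
            out[spec.name] = spec
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["libraries"] = [asdict(l) if isinstance(l, LibrarySpec) else dict(l)
                          for l in self.libraries]
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
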