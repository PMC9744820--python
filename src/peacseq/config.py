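"""Pipeline configuration: one YAML-serializable object carrying the tag
design, primer set, thresholds and simulator parameters for every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .readprep import DEFAULT_TAG, Primer, TagDesign, default_tag_design
from .simulate import LibraryParams
from .sites import CallConfig
from .transloc import TranslocConfig


@dataclass
class SimConfig:
    """Synthetic-library study conditions (defaults are the standard test
    fixture: 100 kb reference, one on-target plus six off-targets carrying
    1-6 mismatches, 50k read pairs)."""

    ref_length: int = 100_000
    gc: float = 0.41
    ref_name: str = "chrS"
    spacer: str = ""            # empty => drawn from the seed
    n_offtargets: int = 6
    mismatch_counts: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_fragments: int = 50_000
    wt_fragments: int = 20_000
    seq_error_rate: float = 0.0
    random_priming_rate: float = 0.02
    background_rate: float = 0.05
    pcr_dup_factor: int = 1
    #: junction specs as (model, donor_offtarget_index, rate); receiver is
    #: always the on-target site
    junctions: tuple[tuple[str, int, float], ...] = ()
    junction_fragments: int = 2_000


@dataclass
class PipelineConfig:
    tag_seq: str = DEFAULT_TAG
    pbs_len: int = 13
    #: (primer_id, sequence, side, boundary_offset); empty => default panel
    primers: tuple[tuple[str, str, str, int], ...] = ()
    enrichment_primers: tuple[str, str] = ("F1", "R2")
    umi_len: int = 10
    max_mm_primer: int = 1
    seed: int = 0
    call: CallConfig = field(default_factory=CallConfig)
    transloc: TranslocConfig = field(default_factory=TranslocConfig)
    sim: SimConfig = field(default_factory=SimConfig)

    def tag_design(self) -> TagDesign:
        if not self.primers:
            return dataclasses.replace(default_tag_design(self.tag_seq), pbs_len=self.pbs_len)
        primers = tuple(Primer(pid, seq, side, off) for pid, seq, side, off in self.primers)
        return TagDesign(tag_seq=self.tag_seq, pbs_len=self.pbs_len, primers=primers)

    def library_params(self, n_fragments: int | None = None, seed: int | None = None) -> LibraryParams:
        s = self.sim
        return LibraryParams(
            n_fragments=n_fragments if n_fragments is not None else s.n_fragments,
            seq_error_rate=s.seq_error_rate,
            random_priming_rate=s.random_priming_rate,
            background_rate=s.background_rate,
            pcr_dup_factor=s.pcr_dup_factor,
            umi_len=self.umi_len,
            seed=self.seed if seed is None else seed,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "call" in d and isinstance(d["call"], dict):
            d["call"] = CallConfig(**d["call"])
        if "transloc" in d and isinstance(d["transloc"], dict):
            d["transloc"] = TranslocConfig(**d["transloc"])
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if "mismatch_counts" in sim:
                sim["mismatch_counts"] = tuple(sim["mismatch_counts"])
            if "junctions" in sim:
                sim["junctions"] = tuple(tuple(j) for j in sim["junctions"])
            d["sim"] = SimConfig(**sim)
        if "primers" in d:
            d["primers"] = tuple(tuple(p) for p in d["primers"])
        if "enrichment_primers" in d:
            d["enrichment_primers"] = tuple(d["enrichment_primers"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def params_hash(self) -> str:
        """Stable hash of all parameters, for manifests/reproducibility."""
        return hashlib.sha256(
            json.dumps(_plain(self.to_dict()), sort_keys=True).encode()
        ).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples to lists so YAML/JSON round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
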