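"""Run configuration: every calling, filtering and QC threshold in one
place, with the pipeline's validated defaults.

Defaults (all overridable per run):

=====================  =======  ==================================================
knob                   default  meaning
=====================  =======  ==================================================
qt_min / qt_max        20 / 30  base-quality floors swept by the SNV caller
score_threshold        50       Phred-scaled binomial score a call must exceed
min_coverage           150      minimum depth to attempt a call
sr_low                 2.0      %SR below which a call is low-confidence
indel_homopolymer_len  6        homopolymer run length that flags low-%SR InDels
indel_sr_min           10.0     %SR below which the homopolymer filter applies
tail_bias_p            1e-5     rank-sum p below which tail-distance bias filters
cnv_amp / cnv_del      2.7/1.2  gene copy-number thresholds (diploid = 2)
amp_region_fraction    0.5      fraction of regions that must exceed cnv_amp
sv_min_support         8        consistent split reads required to report a fusion
ct_max                 0.45     C>T fraction above which a sample fails QC
nvar_max               500      variant count (>=5 %SR) above which QC fails
=====================  =======  ==================================================
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SNVConfig:
    qt_min: int = 20
    qt_max: int = 30
    score_threshold: float = 50.0
    min_coverage: int = 150
    sr_low: float = 2.0
    indel_homopolymer_len: int = 6
    indel_sr_min: float = 10.0
    tail_bias_p: float = 1e-5
    min_mapping_quality: int = 0

    def validate(self) -> None:
        if self.qt_min > self.qt_max:
            raise ConfigError("qt_min must be <= qt_max")
        if self.score_threshold < 0 or self.min_coverage < 1:
            raise ConfigError("bad SNV thresholds")

    @property
    def qt_range(self) -> range:
        return range(self.qt_min, self.qt_max + 1)


@dataclass
class CNVConfig:
    amp_threshold: float = 2.7
    del_threshold: float = 1.2
    amp_region_fraction: float = 0.5
    z_cutoff: float = 3.0
    deviant_region_fraction: float = 0.10  # of manifest regions, per profile iteration
    sd_floor_fraction: float = 0.05
    gc_bin_width: float = 0.02

    def validate(self) -> None:
        if not self.amp_threshold > 2.0 > self.del_threshold > 0.0:
            raise ConfigError("need amp > 2 > del > 0")


@dataclass
class SVConfig:
    min_support: int = 8
    breakpoint_tolerance: int = 5
    min_segment_span: int = 25
    min_intergene_distance: int = 100_000

    def validate(self) -> None:
        if self.min_support < 1:
            raise ConfigError("sv min_support must be >= 1")


@dataclass
class QCConfig:
    ct_max: float = 0.45
    nvar_max: int = 500
    qc_sr_min: float = 5.0          # %SR floor for the artifact metrics
    count_ga_with_ct: bool = True   # deamination seen on either strand

    def validate(self) -> None:
        if not 0 < self.ct_max <= 1:
            raise ConfigError("ct_max must be in (0, 1]")


@dataclass
class LODConfig:
    replicates: int = 200

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


@dataclass
class RunConfig:
    """Aggregate configuration for a pipeline run."""

    snv: SNVConfig = field(default_factory=SNVConfig)
    cnv: CNVConfig = field(default_factory=CNVConfig)
    sv: SVConfig = field(default_factory=SVConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    lod: LODConfig = field(default_factory=LODConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        for section in (self.snv, self.cnv, self.sv, self.qc, self.lod):
            section.validate()
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in d.items():
            if key not in known:
                raise ConfigError(f"unknown config section {key!r}")
            if key == "seed":
                kwargs["seed"] = int(val)
                continue
            section_cls = {"snv": SNVConfig, "cnv": CNVConfig, "sv": SVConfig,
                           "qc": QCConfig, "lod": LODConfig}[key]
            names = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(val) - names
            if bad:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
            kwargs[key] = section_cls(**val)
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
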