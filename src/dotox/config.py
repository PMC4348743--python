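"""Run configuration: every stage parameter with a serializable default."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Defaults encode the study conditions: two cohorts of generation-7/8
    outbred mice, four exposure concentrations, a dominant protective QTL on
    chromosome 10 sized to ~49% of the top-dose variance, pre-exposure
    heritability 0.65, and log-normal benchmark-concentration modeling with
    the high-dose-drop rule.
    """

    seed: int = 1

    # genome / simulation
    n_mice: int = 600
    generation: int = 8
    n_chromosomes: int = 10
    markers_per_chromosome: int = 90
    chromosome_length_mb: float = 90.0
    private_interval: tuple = (10, 28.0, 36.0)
    genotype_error_rate: float = 0.002
    genotype_missing_rate: float = 0.053
    genotype_missing_rate_sd: float = 0.012

    # phenotype model
    doses: tuple = (0.0, 1.0, 10.0, 100.0)
    exp_a: float = 2.5
    exp_b: float = 0.018
    exp_c: float = 6.0
    sigma_log: float = 0.35
    h2_target: float = 0.65

    # planted QTL
    qtl_on: bool = True
    qtl_chromosome: int = 10
    qtl_position_mb: float = 31.87
    qtl_founder: str = "F"
    qtl_mode: str = "dominant"
    qtl_var_frac: float = 0.49

    # QC / HMM
    qc_call_rate_threshold: float = 0.90
    hmm_error_rate: float = 0.002

    # scan
    n_perm: int = 1000
    alpha: float = 0.05
    scan_covariate_cohort: bool = True

    # BMC
    bmc_distribution: str = "lognormal"
    bmc_bmr: str = "rel10"
    bmc_drop_high_dose: bool = True
    bmc_level: float = 0.95

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("private_interval", "doses"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)
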