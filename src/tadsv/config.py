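"""Pipeline configuration.

Every numeric parameter used across the pipeline lives in
:class:`PipelineConfig`, so a run is fully described by one config object
plus its input files and root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping


#: Default mapping of the 15 chromatin-state labels onto coarse activity tags.
#: Keys are state indices 1..15 (Roadmap-style core model ordering: TssA,
#: TssAFlnk, TxFlnk, Tx, TxWk, EnhG, Enh, ZNF/Rpts, Het, TssBiv, BivFlnk,
#: EnhBiv, ReprPC, ReprPCWk, Quies).  Used only for naming k-means clusters.
DEFAULT_STATE_DICTIONARY: dict[int, str] = {
    1: "active", 2: "active", 3: "active", 4: "active", 5: "active",
    6: "active", 7: "active",
    8: "neutral",
    9: "quiescent",
    10: "neutral", 11: "neutral", 12: "neutral", 13: "neutral", 14: "neutral",
    15: "quiescent",
}

#: Domain class names ordered from least to most transcriptionally active.
DOMAIN_CLASS_ORDER: tuple[str, ...] = (
    "heterochromatin", "low", "repressed", "low-active", "active",
)


@dataclass
class PipelineConfig:
    """All tunable parameters of the TAD-disruption pipeline.

    Lengths are in base pairs.  Parameters whose semantics are bin-aligned
    (windows, spans, boundary width) must be positive multiples of
    ``bin_size``; :meth:`validate` enforces this.
    """

    bin_size: int = 25_000
    tad_signal_window: int = 2_000_000
    insulation_square: int = 1_000_000      # square edge for insulation score
    delta_span: int = 200_000               # span for the insulation delta
    insulation_mean: str = "mean"           # window statistic (mean supported)
    boundary_margin: int = 1                # merge margin, in bins
    noise_threshold: float = 0.1            # minimum boundary strength
    consensus_tol: int = 50_000             # consensus grouping tolerance
    boundary_width: int = 75_000            # emitted boundary interval (3 bins)
    short_range_cutoff: int = 2_000_000
    n_shuffles: int = 10_000
    germline_len_range: tuple[int, int] = (75_000, 250_000)
    recurrence_frac: float = 0.10
    kmeans_k: int = 5
    kmeans_restarts: int = 50
    fpkm_min: float = 0.1
    cn_max: float = 4.0
    max_gene_distance: int = 1_000_000
    fusion_window: int = 2_000_000
    scaling_min: float = 0.1
    min_window_unmasked_frac: float = 0.25  # insulation square validity
    rng_seed: int = 0
    state_dictionary: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_STATE_DICTIONARY)
    )

    _BIN_ALIGNED = (
        "tad_signal_window", "insulation_square", "delta_span",
        "boundary_width", "short_range_cutoff", "fusion_window",
    )

    def validate(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name in self._BIN_ALIGNED:
            v = getattr(self, name)
            if v <= 0 or v % self.bin_size:
                raise ValueError(
                    f"{name}={v} must be a positive multiple of bin_size={self.bin_size}"
                )
        if self.insulation_mean != "mean":
            raise ValueError("only the 'mean' window statistic is supported")
        lo, hi = self.germline_len_range
        if not 0 < lo <= hi:
            raise ValueError("germline_len_range must satisfy 0 < lo <= hi")

    # -- derived bin quantities ------------------------------------------
    @property
    def square_bins(self) -> int:
        return self.insulation_square // self.bin_size

    @property
    def delta_bins(self) -> int:
        return self.delta_span // self.bin_size

    @property
    def boundary_bins(self) -> int:
        return self.boundary_width // self.bin_size

    def to_dict(self) -> dict:
        d = asdict(self)
        d["state_dictionary"] = dict(self.state_dictionary)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown config keys: {sorted(bad)}")
        kwargs = dict(d)
        if "germline_len_range" in kwargs:
            kwargs["germline_len_range"] = tuple(kwargs["germline_len_range"])
        if "state_dictionary" in kwargs:
            kwargs["state_dictionary"] = {
                int(k): v for k, v in dict(kwargs["state_dictionary"]).items()
            }
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
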