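"""The production simulation protocol shape this pipeline's cohorts emulate.

A cohort covers every catalogued mutation plus WT, each simulated in both
nucleotide states with three independent replicates of fixed production
length.  These constants describe the emulated study design; the synthetic
generator produces desk-scale stand-ins with the same (variant, state,
replicate) shape.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ProductionProtocol", "DEFAULT_PROTOCOL", "total_simulated_time_us"]


@dataclass(frozen=True)
class ProductionProtocol:
    n_mutants: int = 86
    include_wt: bool = True
    n_states: int = 2  # GDP- and GTP-bound
    n_replicates: int = 3
    production_ns: float = 40.0  # unrestrained production length per run

    @property
    def n_systems(self) -> int:
        return self.n_mutants + (1 if self.include_wt else 0)

    @property
    def n_runs(self) -> int:
        return self.n_systems * self.n_states * self.n_replicates

    @property
    def total_time_us(self) -> float:
        return self.n_runs * self.production_ns / 1000.0


DEFAULT_PROTOCOL = ProductionProtocol()


def total_simulated_time_us(protocol: ProductionProtocol = DEFAULT_PROTOCOL) -> float:
    """Total production time implied by the protocol, in microseconds."""
    return protocol.total_time_us
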