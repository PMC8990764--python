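"""Small configurable designs and single-response configs used across tests."""

from mixtrial.model import MIXTURE, MONO_WHEAT, EntryInfo, TrialDesign
from mixtrial.simulate import ResponseSpec, SimulationConfig


def small_design(n_entries=15, n_blocks=4, seasons=("s1",)):
    entries = tuple(EntryInfo(f"E{i:02d}", "line", "C-lines")
                    for i in range(n_entries))
    return TrialDesign(seasons=seasons, entries=entries, n_blocks=n_blocks)


def yield_config(design, system_effect=-1.0, sd_block=0.15, sd_mainplot=0.1,
                 sd_residual=0.3, seed=0, interaction=None):
    """One-response config: wheat yield with an additive mixture shift and
    equally spaced, zero-sum entry effects (0.05 apart)."""
    season = design.seasons[0]
    return SimulationConfig(
        design=design,
        responses={
            "wheat_yield": ResponseSpec(
                means={(season, MONO_WHEAT): 4.2,
                       (season, MIXTURE): 4.2 + system_effect},
                entry_effects={
                    e: 0.05 * i - 0.05 * (len(design.entries) - 1) / 2
                    for i, e in enumerate(design.entry_names)},
                interaction=interaction or {},
                sd_block=sd_block, sd_mainplot=sd_mainplot,
                sd_residual=sd_residual),
        },
        rng_seed=seed,
    )
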