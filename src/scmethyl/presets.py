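"""Desk-scale model and training presets.

One place defines the small-model conditions used by the test suite, the
acceptance script and the CLI examples, so every consumer runs the same
experiment.  The published-scale defaults (1001 bp windows, 128/256 filters,
256-unit GRU) remain the dataclass defaults in their modules; these presets
are the configurations a laptop CPU can train in minutes on the synthetic
fixtures.
"""

from __future__ import annotations

from .cpg_net import CpgNetConfig
from .dna_net import DnaNetConfig
from .joint_training import TrainConfig

#: Window length for desk-scale DNA models; matches the span within which
#: the motif fixture's sequence effects act.
DESK_L_WIN = 201

#: Window length for the variance-network experiments (the mean/variance
#: targets are window-scale, so the input must span the smallest target
#: window).
VAR_L_WIN = 1001

#: Neighbours per side for desk-scale CpG contexts.
DESK_K = 10

#: Random restarts for conv-net training (selected by validation AUC).
DESK_RESTARTS = 3


def desk_dna_config() -> DnaNetConfig:
    """One conv-pool pair: 32 length-11 filters, pool 47, 32 FC units.

    The large pool makes the representation near position-invariant, which
    is what lets a network trained on ~1000 sites generalise across
    chromosomes instead of memorising filter positions.
    """
    return DnaNetConfig(n_conv_pool_pairs=1, filters_per_layer=[32],
                        filter_lengths=[11], pool_size=47, fc_units=32,
                        dropout_rate=0.25)


def desk_cpg_config() -> CpgNetConfig:
    return CpgNetConfig(embed_units=32, hidden_units=32, dropout_rate=0.1)


def desk_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(seed=seed, batch_size=128, learning_rate=3e-3,
                       lr_decay_per_epoch=0.995,
                       early_stop_patience_epochs=40, max_epochs=300,
                       l2_lambda=0.03)


def desk_cpg_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(seed=seed, batch_size=128, learning_rate=3e-3,
                       lr_decay_per_epoch=0.995,
                       early_stop_patience_epochs=20, max_epochs=200,
                       l2_lambda=0.01)


def desk_joint_units() -> int:
    return 64


def desk_varnet_train_config(seed: int = 0) -> TrainConfig:
    """Fine-tuning budget for the mean/variance network.

    A fixed 80-epoch budget (no early stopping): the positionally blocked
    validation strip holds too few independent kilobase-scale windows to
    steer stopping for a window-scale regression.
    """
    return TrainConfig(seed=seed, batch_size=128, learning_rate=3e-3,
                       lr_decay_per_epoch=0.99,
                       early_stop_patience_epochs=80, max_epochs=80,
                       l2_lambda=0.3)
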