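{
 "train": {"learning_rate": 0.003, "lr_decay_per_epoch": 0.995,
           "early_stop_patience_epochs": 40, "max_epochs": 300,
           "l2_lambda": 0.03},
 "dna": {"n_conv_pool_pairs": 1, "filters_per_layer": [32],
         "filter_lengths": [11], "pool_size": 47, "fc_units": 32,
         "dropout_rate": 0.25},
 "cpg": {"embed_units": 32, "hidden_units": 32, "dropout_rate": 0.1},
 "joint_units": 64
}
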