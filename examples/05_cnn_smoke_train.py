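"""Train a scaled-down two-tower CNN on image pairs with a planted signal.

The target is a linear function of the two images' mean intensities plus
noise.  A functioning regressor must beat the mean predictor (predicting
the training-target mean for every pair); the report compares the two.
"""

import tabimg as ti

shape = (24, 24)
spec = ti.CNNSpec(input_shapes=(shape, shape), conv_filters=(4, 8, 8),
                  kernel_size=3, dense_units=(16,), seed=0)
model = ti.build_two_tower_cnn(spec)

a, b, y = ti.generate_paired_image_response(300, shape, shape, seed=5)
report = ti.smoke_train(model, a, b, y, ti.TrainingConfig(seed=5))

print(f"parameters        : {report['n_parameters']:,}")
print(f"mean-predictor MSE: {report['baseline_mse']:.4f}")
print(f"model val MSE     : {report['val_mse']:.4f} (best epoch {report['best_epoch']})")
print(f"beats baseline    : {report['beats_baseline']}")
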