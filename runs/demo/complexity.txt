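complexity report (FLOPs convention: mac2; 4 bytes/param)
layer                       kind                    params trainable       FLOPs
block1.conv_temporal        conv2d                     256       256     4915200
block1.bn_temporal          batch_norm                  16         8       76800
block1.conv_spatial         depthwise_conv2d           256       256      153600
block1.bn_spatial           batch_norm                  32        16        4800
block1.elu                  activation_elu               0         0        2400
block1.pool                 average_pool                 0         0        2400
block1.dropout              dropout                      0         0           0
block2.conv_separable       separable_conv2d           192       192       28800
block2.bn                   batch_norm                  32        16        1200
block2.elu                  activation_elu               0         0         600
block2.pool                 average_pool                 0         0         576
block2.dropout              dropout                      0         0           0
classifier.flatten          flatten                      0         0           0
classifier.dense            dense_softmax              146       146         296
TOTAL                                                  930       890     5186672
totals: 0.000930 M params, 0.005187 G FLOPs, 3720 bytes
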