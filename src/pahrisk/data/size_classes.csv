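size_class,grams_per_shrimp
small,8.172828828828829
medium,9.969054945054945
large,12.777239436619719
extra_large,16.199714285714285
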