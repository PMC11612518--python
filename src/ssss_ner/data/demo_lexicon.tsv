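头昏	头晕
右手中指	右中指
颈动脉彩超	双侧颈动脉彩超
头孢哌酮	头孢哌酮舒巴坦钠
MRI	核磁共振检查
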