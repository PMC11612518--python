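{"id": "demo-1", "text": "右手中指疼痛不适", "entities": [{"start": 0, "end": 4, "type": "Body"}]}
{"id": "demo-2", "text": "主因头部外伤出血伴头昏3.5小时入院", "entities": [{"start": 9, "end": 11, "type": "Symptom"}]}
{"id": "demo-3", "text": "心电图, 颈动脉彩超等检查", "entities": [{"start": 0, "end": 3, "type": "Exam"}, {"start": 5, "end": 10, "type": "Exam"}]}
{"id": "demo-4", "text": "给予静点头孢哌酮, 炎琥宁联合抗感染", "entities": [{"start": 4, "end": 8, "type": "Treatment"}, {"start": 10, "end": 13, "type": "Treatment"}]}
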