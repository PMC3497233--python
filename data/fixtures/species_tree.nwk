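(t00:0.1886329321452188,(((((((t01:0.07516520321767398,t13:0.1352590426181643):0.029461540984873226,t03:0.13654195834182423):0.14462670860210158,((t02:0.027085995417304526,t10:0.13761258779860325):0.09812607046201782,t09:0.0043233961715985255):0.10919561664329967):0.07131265518721833,(t07:0.025342683186346172,t15:0.010020009367645275):0.015679320164525286):0.05078785545262246,t08:0.0758371430976705):0.09096248336418244,(t05:0.012289042149117007,t12:0.1009757847242918):0.11766461293351774):0.031974167764453956,((t06:0.1157484747991978,t11:0.09679709254563544):0.10389660661117513,t14:0.1890724827003578):0.09920817159354829):0.11666178960998326,t04:0.052813234947443936);
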