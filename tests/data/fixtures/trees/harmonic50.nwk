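(((((((((((((((((((((((((((((((((((((((((((((((((L01:0.02,L02:0.02):0.020408163265306121,L03:0.040408163265306121):0.020833333333333329,L04:0.06124149659863945):0.021276595744680854,L05:0.082518092343320304):0.021739130434782608,L06:0.10425722277810291):0.022222222222222213,L07:0.12647944500032512):0.022727272727272735,L08:0.14920671772759786):0.023255813953488358,L09:0.17246253168108622):0.023809523809523808,L10:0.19627205549061003):0.024390243902439018,L11:0.22066229939304904):0.024999999999999994,L12:0.24566229939304904):0.025641025641025633,L13:0.27130332503407467):0.026315789473684237,L14:0.29761911450775891):0.027027027027027029,L15:0.32464614153478594):0.02777777777777779,L16:0.35242391931256373):0.028571428571428581,L17:0.38099534788399231):0.029411764705882359,L18:0.41040711258987467):0.030303030303030332,L19:0.440710142892905):0.03125,L20:0.471960142892905):0.032258064516129004,L21:0.504218207409034):0.033333333333333326,L22:0.53755154074236733):0.034482758620689613,L23:0.57203429936305694):0.035714285714285698,L24:0.60774858507734264):0.03703703703703709,L25:0.64478562211437973):0.038461538461538436,L26:0.68324716057591817):0.040000000000000036,L27:0.7232471605759182):0.04166666666666663,L28:0.76491382724258483):0.043478260869565188,L29:0.80839208811215002):0.045454545454545414,L30:0.85384663356669543):0.047619047619047672,L31:0.90146568118574311):0.050000000000000044,L32:0.95146568118574315):0.052631578947368363,L33:1.0040972601331115):0.05555555555555558,L34:1.0596528156886671):0.058823529411764719,L35:1.1184763451004318):0.0625,L36:1.1809763451004318):0.066666666666666652,L37:1.2476430117670985):0.071428571428571397,L38:1.3190715831956699):0.076923076923076872,L39:1.3959946601187467):0.083333333333333259,L40:1.47932799345208):0.090909090909090828,L41:1.5702370843611708):0.10000000000000009,L42:1.6702370843611709):0.11111111111111116,L43:1.7813481954722821):0.125,L44:1.9063481954722821):0.14285714285714302,L45:2.0492053383294251):0.16666666666666652,L46:2.2158720049960916):0.20000000000000018,L47:2.4158720049960918):0.25,L48:2.6658720049960918):0.33333333333333348,L49:2.9992053383294253):0.5,L50:3.4992053383294253);
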