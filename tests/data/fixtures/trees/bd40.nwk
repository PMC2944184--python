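((t01:4.0752999276265403,((t04:1.6881290601281829,((((t37:0.055715813864112285,t38:0.055715813864112285):0.078148961221040203,t29:0.13386477508515249):0.13620514921148885,(t21:0.19568598069888843,t22:0.19568598069888843):0.074383943597752911):0.029837145960426525,t16:0.29990707025706786):1.388221989871115):1.9610570620211529,((t07:1.3507999055826829,(t09:0.5607919455802417,t10:0.5607919455802417):0.79000796000244122):0.77847018863429307,((t17:0.34674640823341996,(t30:0.13377822074521717,t31:0.13377822074521717):0.21296818748820279):1.5050485641068225,(t20:1.2627169529026112,t05:1.2627169529026112):0.58907801943763127):0.27747512187673351):1.5199160279323598):0.42611380547720445):1.4103676524053892,((((t25:0.18811858294183725,t26:0.18811858294183725):0.14991866413948429,t14:0.33803724708132155):2.376574949548425,((((t27:0.16098472919864104,t28:0.16098472919864104):0.14822935736322496,t15:0.309214086561866):0.86464128973665133,(((t18:0.26976060993307982,t19:0.26976060993307982):0.24525863841265139,t12:0.51501924834573121):0.20374647005153967,t06:0.71876571839727088):0.45508965790124645):0.7240885499837395,(t23:0.18946059353157008,t24:0.18946059353157008):1.7084833327506868):0.81666827034748968):2.1691922327054383,(((((t39:0.043881232567918538,t40:0.043881232567918538):0.64986101624952397,(t35:0.055898501171207648,t36:0.055898501171207648):0.63784374764623486):0.97444824878899139,t11:1.6681904976064339):1.0574097304887009,(t02:2.2714886798579927,t03:2.2714886798579927):0.45411154823714206):0.11226988919216918,(t08:0.65292662654949751,(t13:0.48328287943391857,(t32:0.11909150576781524,(t33:0.11537229075997679,t34:0.11537229075997679):0.00371921500783845):0.36419137366610332):0.16964374711557895):2.1849434907378065):2.0459343120478808):0.60186315069674468);
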